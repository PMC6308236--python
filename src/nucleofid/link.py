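"""Frame-to-frame correspondence and the full-duration persistence filter.

Linking is deliberately conservative, mirroring the analysis it reproduces:
detections in consecutive frames are paired one-to-one greedily in ascending
order of distance (no gap closing, no merging/splitting, no motion model),
pairs farther apart than ``max_link_distance`` stay unlinked, and only tracks
present in every frame of the movie survive the persistence filter.  At
multi-minute frame intervals chromatin loci move far less than the spot
spacing, so greedy matching equals optimal matching in the regime the
experiment operates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import Detection
from .errors import EmptyResultError, ParameterError

__all__ = ["CandidateTrack", "Track", "TrackSet", "link_frames", "filter_persistent"]

TRACK_COLUMNS = (
    "cell_id",
    "track_id",
    "probe",
    "condition",
    "frame",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
)


@dataclass
class CandidateTrack:
    """A chain of linked detections; may not span the full movie."""

    start_frame: int
    xy: list  # list of (x, y)
    detections: list = field(default_factory=list)

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.xy) - 1

    def positions(self) -> np.ndarray:
        return np.asarray(self.xy, dtype=float)


@dataclass
class Track:
    """A persistent trajectory: one planar position per frame, no gaps."""

    cell_id: int
    track_id: int
    probe: str
    condition: str
    xy_um: np.ndarray  # (n_frames, 2)
    frame_interval: float
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.xy_um.shape[0]


@dataclass
class TrackSet:
    """Persistent tracks grouped by cell and condition."""

    tracks: list
    n_frames: int
    frame_interval: float
    pixel_size: float

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def n_cells(self) -> int:
        return len({t.cell_id for t in self.tracks})

    def per_cell_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.tracks:
            out[t.cell_id] = out.get(t.cell_id, 0) + 1
        return out

    def subset(self, probe: str | None = None, condition: str | None = None):
        kept = [
            t
            for t in self.tracks
            if (probe is None or t.probe == probe)
            and (condition is None or t.condition == condition)
        ]
        return TrackSet(kept, self.n_frames, self.frame_interval, self.pixel_size)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f in range(t.n_frames):
                rows.append(
                    {
                        "cell_id": t.cell_id,
                        "track_id": t.track_id,
                        "probe": t.probe,
                        "condition": t.condition,
                        "frame": f,
                        "x_px": t.xy_um[f, 0] / t.pixel_size,
                        "y_px": t.xy_um[f, 1] / t.pixel_size,
                        "x_um": t.xy_um[f, 0],
                        "y_um": t.xy_um[f, 1],
                    }
                )
        return pd.DataFrame(rows, columns=list(TRACK_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float, pixel_size: float):
        tracks = []
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        for (cell, tid, probe, cond), g in df.groupby(
            ["cell_id", "track_id", "probe", "condition"], sort=True
        ):
            g = g.sort_values("frame")
            tracks.append(
                Track(
                    cell_id=int(cell),
                    track_id=int(tid),
                    probe=str(probe),
                    condition=str(cond),
                    xy_um=g[["x_um", "y_um"]].to_numpy(dtype=float),
                    frame_interval=frame_interval,
                    pixel_size=pixel_size,
                )
            )
        return cls(tracks, n_frames, frame_interval, pixel_size)


def _frame_positions(dets) -> np.ndarray:
    if len(dets) == 0:
        return np.empty((0, 2))
    if isinstance(dets[0], Detection):
        pts = np.array([[d.x, d.y] for d in dets], dtype=float)
    else:
        pts = np.asarray(dets, dtype=float).reshape(-1, 2)
    # canonical within-frame order makes tie-breaking independent of input order
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def link_frames(detections_per_frame, max_link_distance: float) -> list:
    """Build candidate tracks by greedy nearest-neighbor frame-to-frame linking.

    ``detections_per_frame``: sequence over frames, each a list of
    :class:`~nucleofid.detect.Detection` or an (n, 2) array of positions (px).
    Pairs are assigned one-to-one in ascending distance; pairs farther than
    ``max_link_distance`` stay unassigned and start new candidates.  Ties are
    broken by (distance, track order, detection coordinates), and detections
    are canonicalized by position first, so the output is invariant to the
    listing order within a frame.
    """
    if max_link_distance <= 0:
        raise ParameterError("max_link_distance must be > 0")
    frames = [_frame_positions(d) for d in detections_per_frame]
    if not frames:
        return []
    active: list[CandidateTrack] = [
        CandidateTrack(0, [tuple(p)]) for p in frames[0]
    ]
    closed: list[CandidateTrack] = []
    for t in range(1, len(frames)):
        pts = frames[t]
        ends = np.array([c.xy[-1] for c in active], dtype=float).reshape(-1, 2)
        pairs = []
        if len(active) and len(pts):
            d2 = ((ends[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            for i in range(len(active)):
                for j in range(len(pts)):
                    if d2[i, j] <= max_link_distance**2:
                        pairs.append((d2[i, j], i, j))
            pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for _, i, j in pairs:
            if i in used_tracks or j in used_dets:
                continue
            active[i].xy.append(tuple(pts[j]))
            used_tracks.add(i)
            used_dets.add(j)
        still_active = []
        for i, c in enumerate(active):
            (still_active if i in used_tracks else closed).append(c)
        for j in range(len(pts)):
            if j not in used_dets:
                still_active.append(CandidateTrack(t, [tuple(pts[j])]))
        active = still_active
    return closed + active


def filter_persistent(
    candidates,
    n_frames: int,
    *,
    cell_id: int = 0,
    probe: str = "",
    condition: str = "",
    frame_interval: float = 3.0,
    pixel_size: float = 0.1,
    allow_empty: bool = False,
) -> TrackSet:
    """Keep only tracks with one position in every frame of the movie.

    Raises :class:`EmptyResultError` if nothing survives (downstream averaging
    would be meaningless), unless ``allow_empty`` is set.
    """
    kept = []
    tid = 0
    for c in candidates:
        if c.start_frame == 0 and len(c.xy) == n_frames:
            kept.append(
                Track(
                    cell_id=cell_id,
                    track_id=tid,
                    probe=probe,
                    condition=condition,
                    xy_um=c.positions() * pixel_size,
                    frame_interval=frame_interval,
                    pixel_size=pixel_size,
                )
            )
            tid += 1
    if not kept and not allow_empty:
        raise EmptyResultError(
            "link", f"no persistent tracks spanning all {n_frames} frames"
        )
    return TrackSet(kept, n_frames, frame_interval, pixel_size)
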