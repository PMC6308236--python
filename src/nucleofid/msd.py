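"""Mean-squared-displacement statistics for persistent particle tracks.

The central quantity is

    MSD(tau) = < (x_{t+tau} - x_t)^2 + (y_{t+tau} - y_t)^2 >

computed per track as a time average over all overlapping (t, t+tau) pairs,
then averaged within each cell, then across cells (the ensemble).  Error bars
are the SEM over cells, so n is the number of cells analyzed.  Tracks whose
MSD at the final reported lag lies more than 3 sample SDs from the ensemble
mean at that lag are excluded in a single pass before averaging.  Group
curves are compared lag-by-lag with a two-sided pooled-variance Student's
t-test on the per-cell values, uncorrected for multiple lags (a Bonferroni
option exists but is off by default).  A log-log power-law fit
MSD = 4 D tau^alpha summarizes each ensemble curve, and turning-angle
statistics (mean resultant length and a Rayleigh uniformity test) probe for
directional persistence of the motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .link import Track, TrackSet

__all__ = [
    "MSDCurve",
    "ComparisonResult",
    "PowerLawFit",
    "DirectionalityResult",
    "track_msd",
    "remove_outliers",
    "cell_average",
    "ensemble_msd",
    "compare_msd",
    "fit_power_law",
    "turning_angles",
    "rayleigh_test",
    "directionality",
]


# ---------------------------------------------------------------------- types
@dataclass
class MSDCurve:
    """MSD(tau) at one level of averaging (track, cell or ensemble)."""

    lags: np.ndarray  # minutes, multiples of the frame interval
    values: np.ndarray  # um^2
    level: str  # "track" | "cell" | "ensemble"
    sem: np.ndarray | None = None  # per-lag SEM over cells (ensemble only)
    n_cells: int | None = None
    cell_id: int | None = None
    track_id: int | None = None
    included_track_ids: list | None = None
    excluded_track_ids: list | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ParameterError("lags and values must have the same shape")
        if np.any(np.diff(self.lags) <= 0):
            raise ParameterError("lags must be strictly increasing")

    def value_at(self, lag: float) -> float:
        idx = np.nonzero(np.isclose(self.lags, lag))[0]
        if idx.size == 0:
            raise ParameterError(f"lag {lag} not present in curve")
        return float(self.values[idx[0]])


@dataclass
class ComparisonResult:
    """Per-lag two-sample Student's t comparison of two groups of cells."""

    lags: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    significant: np.ndarray  # p < alpha_level per lag
    alpha_level: float = 0.05
    degenerate: np.ndarray | None = None  # zero-variance-equal-means flags

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lags,
                "t": self.t,
                "p": self.p,
                "n_a": self.n_a,
                "n_b": self.n_b,
                "significant": self.significant,
            }
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on (log tau, log MSD): MSD = 4 * d_hat * tau^alpha_hat."""

    alpha_hat: float
    d_hat: float
    fit_lag_range: tuple[float, float]
    r_squared: float


@dataclass
class DirectionalityResult:
    """Pooled turning-angle statistics over a set of tracks."""

    angles: np.ndarray  # pooled turning angles, radians, in (-pi, pi]
    resultant_length: float  # R in [0, 1]
    rayleigh_p: float
    mean_angle: float
    n_angles: int
    n_skipped: int  # zero-length displacements encountered
    per_track_p: np.ndarray | None = None


# ------------------------------------------------------------------ track MSD
def _msd_values(xy: np.ndarray, max_lag: int) -> np.ndarray:
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        out[k - 1] = float(np.mean(np.sum(d * d, axis=1)))
    return out


def track_msd(
    track, frame_interval: float | None = None, max_lag_fraction: float = 1 / 3,
    max_lag: int | None = None,
) -> MSDCurve:
    """Time-averaged MSD of one track over all overlapping displacement pairs.

    ``track`` may be a :class:`~nucleofid.link.Track` or an (n_frames, 2)
    coordinate array (um) with ``frame_interval`` given.  Lags run from one
    frame up to ``max_lag`` frames (default: ``max_lag_fraction`` of the
    track length, at least 1).
    """
    if isinstance(track, Track):
        xy = track.xy_um
        dt = track.frame_interval
        meta = dict(cell_id=track.cell_id, track_id=track.track_id)
    else:
        xy = np.asarray(track, dtype=float)
        if frame_interval is None:
            raise ParameterError("frame_interval required for bare coordinate arrays")
        dt = frame_interval
        meta = {}
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ParameterError("track must be an (n_frames, 2) array")
    n = xy.shape[0]
    if n < 2:
        raise ParameterError("track must have at least 2 frames")
    if max_lag is None:
        max_lag = max(1, int(math.floor((n - 1) * max_lag_fraction)))
    max_lag = min(max_lag, n - 1)
    lags = dt * np.arange(1, max_lag + 1)
    return MSDCurve(lags=lags, values=_msd_values(xy, max_lag), level="track", **meta)


# ------------------------------------------------------------------- outliers
def remove_outliers(
    track_curves, final_lag: float | None = None, n_sd: float = 3.0
):
    """Single-pass exclusion of tracks far from the ensemble at the final lag.

    The mean and sample SD of MSD(final_lag) are computed once over all
    curves (each candidate included); curves deviating by more than
    ``n_sd`` SDs are excluded.  Not iterated.  Returns (included, excluded).
    """
    curves = list(track_curves)
    if len(curves) < 2:
        raise ParameterError("need at least 2 curves for outlier screening")
    if final_lag is None:
        final_lag = min(float(c.lags[-1]) for c in curves)
    vals = np.array([c.value_at(final_lag) for c in curves])
    sd = float(vals.std(ddof=1))
    if sd == 0:
        return curves, []
    dev = np.abs(vals - vals.mean())
    included = [c for c, d in zip(curves, dev) if d <= n_sd * sd]
    excluded = [c for c, d in zip(curves, dev) if d > n_sd * sd]
    return included, excluded


# ------------------------------------------------------------------ averaging
def _common_lags(curves) -> np.ndarray:
    n = min(c.lags.size for c in curves)
    lags = curves[0].lags[:n]
    for c in curves:
        if not np.allclose(c.lags[:n], lags):
            raise ParameterError("curves have incompatible lag grids")
    return lags


def cell_average(track_curves) -> list[MSDCurve]:
    """Average track curves within each cell -> one curve per cell."""
    by_cell: dict[int, list[MSDCurve]] = {}
    for c in track_curves:
        if c.cell_id is None:
            raise ParameterError("track curves need cell_id for cell averaging")
        by_cell.setdefault(c.cell_id, []).append(c)
    out = []
    for cell in sorted(by_cell):
        group = by_cell[cell]
        lags = _common_lags(group)
        vals = np.mean([c.values[: lags.size] for c in group], axis=0)
        out.append(MSDCurve(lags=lags, values=vals, level="cell", cell_id=cell))
    return out


def ensemble_msd(track_curves, outliers_removed: bool = True) -> MSDCurve:
    """Cell-then-ensemble average with SEM over cells.

    Track curves are averaged within each cell; cell curves are averaged into
    the ensemble; SEM(tau) = SD over cell curves / sqrt(n_cells).  Outlier
    screening is expected to have been applied already.
    """
    cells = cell_average(track_curves)
    if len(cells) < 2:
        raise ParameterError("ensemble MSD needs at least 2 cells")
    lags = _common_lags(cells)
    mat = np.stack([c.values[: lags.size] for c in cells])
    n = mat.shape[0]
    included = sorted(
        {c.track_id for c in track_curves if c.track_id is not None}
    )
    return MSDCurve(
        lags=lags,
        values=mat.mean(axis=0),
        level="ensemble",
        sem=mat.std(axis=0, ddof=1) / math.sqrt(n),
        n_cells=n,
        included_track_ids=included or None,
    )


# ----------------------------------------------------------------- comparison
def compare_msd(
    group_a, group_b, alpha_level: float = 0.05, bonferroni: bool = False
) -> ComparisonResult:
    """Lag-by-lag two-sided pooled-variance Student's t-test.

    ``group_a`` / ``group_b``: lists of per-cell MSD curves, or 2-D arrays of
    shape (n_cells, n_lags) sharing a lag grid (then pass curves for lags).
    No correction across lags by default, matching the convention of
    reporting each time point independently.
    """
    lags, a = _group_matrix(group_a)
    lags_b, b = _group_matrix(group_b)
    n = min(lags.size, lags_b.size)
    if not np.allclose(lags[:n], lags_b[:n]):
        raise ParameterError("groups have incompatible lag grids")
    lags = lags[:n]
    a, b = a[:, :n], b[:, :n]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ParameterError("both groups need >= 2 cells")
    t = np.empty(n)
    p = np.empty(n)
    degen = np.zeros(n, dtype=bool)
    for k in range(n):
        va, vb = a[:, k], b[:, k]
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            if np.isclose(va.mean(), vb.mean()):
                t[k], p[k], degen[k] = 0.0, 1.0, True
                continue
            t[k], p[k], degen[k] = np.inf, 0.0, True
            continue
        res = stats.ttest_ind(va, vb, equal_var=True)
        t[k], p[k] = float(res.statistic), float(res.pvalue)
    if bonferroni:
        p = np.minimum(p * n, 1.0)
    return ComparisonResult(
        lags=lags,
        t=t,
        p=p,
        n_a=np.full(n, a.shape[0]),
        n_b=np.full(n, b.shape[0]),
        significant=p < alpha_level,
        alpha_level=alpha_level,
        degenerate=degen,
    )


def _group_matrix(group):
    curves = list(group)
    if not curves:
        raise ParameterError("empty group")
    lags = _common_lags(curves)
    return lags, np.stack([c.values[: lags.size] for c in curves])


# ------------------------------------------------------------------ power law
def fit_power_law(
    curve: MSDCurve, fit_lag_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """Fit MSD = 4 * D * tau^alpha by least squares on (log tau, log MSD)."""
    lags, vals = curve.lags, curve.values
    if fit_lag_range is not None:
        keep = (lags >= fit_lag_range[0]) & (lags <= fit_lag_range[1])
        lags, vals = lags[keep], vals[keep]
    if lags.size < 3:
        raise ParameterError("power-law fit needs >= 3 MSD points")
    if np.any(vals <= 0):
        raise ParameterError("power-law fit requires strictly positive MSD values")
    lx, ly = np.log(lags), np.log(vals)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        alpha_hat=float(slope),
        d_hat=float(np.exp(intercept) / 4.0),
        fit_lag_range=(float(lags[0]), float(lags[-1])),
        r_squared=r2,
    )


# -------------------------------------------------------------- directionality
def turning_angles(xy: np.ndarray) -> tuple[np.ndarray, int]:
    """Signed angles between successive displacement vectors of one track.

    Returns (angles in (-pi, pi], number of angles skipped because one of the
    two displacements had zero length).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 3:
        raise ParameterError("turning angles need >= 3 frames")
    v = np.diff(xy, axis=0)
    norms = np.linalg.norm(v, axis=1)
    ok = (norms[:-1] > 0) & (norms[1:] > 0)
    v1, v2 = v[:-1][ok], v[1:][ok]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.sum(v1 * v2, axis=1)
    return np.arctan2(cross, dot), int((~ok).sum())


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for circular uniformity: returns (R, p).

    R is the mean resultant length; p uses the standard Z = n R^2 statistic
    with the Zar/Wilkie finite-sample correction.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ParameterError("no angles")
    C, S = np.cos(angles).sum(), np.sin(angles).sum()
    R = float(np.hypot(C, S) / n)
    z = n * R**2
    p = math.exp(-z) * (
        1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return R, float(min(max(p, 0.0), 1.0))


def directionality(tracks, per_track: bool = True) -> DirectionalityResult:
    """Pooled turning-angle analysis of a TrackSet (or list of xy arrays).

    Isotropic memoryless motion gives uniform turning angles (R near 0,
    Rayleigh p uniform); directional persistence concentrates angles near 0.
    """
    if isinstance(tracks, TrackSet):
        arrays = [t.xy_um for t in tracks.tracks]
    else:
        arrays = [np.asarray(a, dtype=float) for a in tracks]
    if not arrays:
        raise ParameterError("no tracks")
    pooled = []
    skipped = 0
    per_p = []
    for xy in arrays:
        ang, sk = turning_angles(xy)
        skipped += sk
        if ang.size:
            pooled.append(ang)
            if per_track:
                per_p.append(rayleigh_test(ang)[1])
    if not pooled:
        raise ParameterError("no nonzero displacements in any track")
    angles = np.concatenate(pooled)
    R, p = rayleigh_test(angles)
    mean_angle = float(np.arctan2(np.sin(angles).sum(), np.cos(angles).sum()))
    return DirectionalityResult(
        angles=angles,
        resultant_length=R,
        rayleigh_p=p,
        mean_angle=mean_angle,
        n_angles=int(angles.size),
        n_skipped=skipped,
        per_track_p=np.asarray(per_p) if per_track else None,
    )
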