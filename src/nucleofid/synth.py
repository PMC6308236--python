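"""Seeded synthetic nucleus time-lapse generator.

Emulates the experimental design of live-cell chromatin particle tracking:
loci move subdiffusively (fractional Brownian motion, MSD = 4 D tau^alpha)
inside an elliptical nucleus, the whole nucleus drifts and rotates rigidly,
and every chromatin-bound probe is rendered as a Gaussian spot on a noisy
background.  Each "cell" carries one locus-type probe (a tagged chromosomal
site: exactly one track per cell) and one to several bulk-type probes
(nucleolar/telomeric markers: one or multiple tracks per cell), so the
downstream n-accounting (n = cells) can be exercised exactly as in the real
experiment.

Condition presets encode the biology being emulated: transcriptionally
active loci move like bulk chromatin; repressed loci are less mobile; local
DNA damage restores repressed-locus mobility to the bulk level; damage at
active loci raises mobility above bulk at later times, with strongly
heterogeneous per-cell amplitudes (lognormal D) producing the long-lag skew
seen in that condition.  The preset numbers are simulator inputs chosen to
reproduce orderings, not measured values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .transforms import RigidTransformSeries

CONDITIONS = (
    "bulk",
    "active",
    "repressed",
    "damaged-repressed",
    "damaged-active-late",
)


# ---------------------------------------------------------------------- types
@dataclass(frozen=True)
class MotionParams:
    """Fractional-Brownian-motion parameters of one tracked particle.

    alpha : anomalous exponent, MSD ~ tau^alpha, in (0, 2]
    d_app : generalized diffusion coefficient, um^2 / min^alpha
    frame_interval : minutes between frames (3 min by default, the acquisition
        cadence of the emulated experiment)
    n_frames : movie length in frames
    """

    alpha: float
    d_app: float
    frame_interval: float = 3.0
    n_frames: int = 40

    def __post_init__(self):
        if not (0 < self.alpha <= 2):
            raise ParameterError(f"alpha must be in (0, 2], got {self.alpha}")
        if self.d_app < 0:
            raise ParameterError("d_app must be >= 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")


@dataclass
class NucleusScene:
    """Geometry, rigid motion and imaging noise of one synthetic nucleus field.

    Lengths in pixels unless noted.  ``drift_per_frame`` / ``rotation_per_frame``
    may be scalars-per-frame (constant motion) or per-frame arrays of shape
    (n_frames, 2) and (n_frames,) holding the increment applied at each frame
    transition; the cumulative transform at frame t composes frames 1..t.
    """

    center: tuple[float, float] = (64.0, 64.0)
    radii: tuple[float, float] = (34.0, 22.0)
    drift_per_frame: object = (0.2, -0.15)
    rotation_per_frame: object = 0.3  # degrees / frame
    psf_sigma: float = 1.3
    spot_amplitude: float = 1000.0
    background_level: float = 200.0
    read_noise_sd: float | None = None  # default: spot_amplitude / 10
    poisson_noise: bool = False
    pixel_size: float = 0.1  # um / px
    image_shape: tuple[int, int] = (128, 128)
    nucleus_amplitude: float = 2000.0  # counterstain is the brightest channel
    edge_softness: float = 2.0  # px, sigmoid width of the nuclear rim

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise ParameterError("radii must be > 0")
        if self.psf_sigma <= 0:
            raise ParameterError("psf_sigma must be > 0")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def noise_sd(self) -> float:
        return (
            self.spot_amplitude / 10.0
            if self.read_noise_sd is None
            else self.read_noise_sd
        )

    def transform_series(self, n_frames: int) -> RigidTransformSeries:
        """Cumulative rigid motion over ``n_frames`` (frame 0 = identity)."""
        drift = np.asarray(self.drift_per_frame, dtype=float)
        if drift.ndim == 1:
            drift = np.tile(drift, (n_frames - 1, 1))
        if drift.shape != (n_frames - 1, 2):
            raise ParameterError("drift_per_frame must be (2,) or (n_frames-1, 2)")
        rot = np.asarray(self.rotation_per_frame, dtype=float)
        if rot.ndim == 0:
            rot = np.full(n_frames - 1, float(rot))
        if rot.shape != (n_frames - 1,):
            raise ParameterError("rotation_per_frame must be scalar or (n_frames-1,)")
        dx = np.concatenate([[0.0], np.cumsum(drift[:, 0])])
        dy = np.concatenate([[0.0], np.cumsum(drift[:, 1])])
        th = np.concatenate([[0.0], np.cumsum(rot)])
        return RigidTransformSeries(dx, dy, th, tuple(self.center))


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows and the pipeline must recover.

    ``tracks``: DataFrame with one row per (cell, track, frame) holding
    nucleus-fixed positions (x_px, y_px / x_um, y_um) and the lab-frame
    positions actually rendered (lab_x_px, lab_y_px), plus an ``in_bounds``
    flag for spots that were clipped at the image edge.
    """

    tracks: pd.DataFrame
    transforms: dict[int, RigidTransformSeries]
    motion_params: dict[tuple[int, int], MotionParams]
    condition: str
    scene: NucleusScene
    n_frames: int

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.tracks["cell_id"].unique())


@dataclass
class ImageStackSet:
    """Rendered multi-channel movies, one stack of shape (T, C, Y, X) per cell."""

    stacks: dict[int, np.ndarray]
    channels: tuple[str, ...]
    pixel_size: float
    frame_interval: float

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.stacks)

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass(frozen=True)
class FluenceResult:
    fluence_j_m2: float
    energy_j: float | None = None


# ------------------------------------------------------------ fBM simulation
def _fgn_circulant_eigenvalues(n_steps: int, hurst: float) -> np.ndarray:
    k = np.arange(n_steps + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n
    return np.fft.fft(row).real


def _fgn_pairs(n_steps: int, hurst: float, rng: np.random.Generator, n_tracks: int):
    """Return two independent batches of unit-variance fGn, shape (n_tracks, n_steps).

    Circulant embedding: the eigenvalue-weighted FFT of complex white noise has
    the target stationary covariance in its real and imaginary parts
    independently, so one transform serves both spatial axes.  Falls back to a
    Cholesky factorization of the exact Toeplitz covariance (with a warning)
    if the embedding is not nonnegative-definite for this (n, H).
    """
    lam = _fgn_circulant_eigenvalues(n_steps, hurst)
    m = lam.size
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        warnings.warn(
            "circulant embedding not nonnegative-definite; "
            "falling back to exact covariance factorization",
            RuntimeWarning,
            stacklevel=2,
        )
        from scipy.linalg import cholesky, toeplitz

        k = np.arange(n_steps, dtype=float)
        h2 = 2.0 * hurst
        gamma = 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)
        L = cholesky(toeplitz(gamma), lower=True)
        gx = rng.standard_normal((n_tracks, n_steps)) @ L.T
        gy = rng.standard_normal((n_tracks, n_steps)) @ L.T
        return gx, gy
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal((n_tracks, m)) + 1j * rng.standard_normal((n_tracks, m))
    y = np.fft.fft(np.sqrt(lam) * z, axis=-1) / math.sqrt(m)
    return y.real[:, :n_steps], y.imag[:, :n_steps]


def simulate_fbm_tracks(
    params: MotionParams, n_tracks: int, seed
) -> np.ndarray:
    """Simulate ``n_tracks`` planar fBM trajectories, shape (n_tracks, n_frames, 2), um.

    Increments per axis are fractional Gaussian noise with Hurst H = alpha/2,
    scaled so the expected two-dimensional MSD at lag tau is 4 * d_app * tau^alpha.
    Trajectories start at the origin.  Deterministic given the seed.
    """
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = params.n_frames - 1
    sigma = math.sqrt(2.0 * params.d_app * params.frame_interval**params.alpha)
    if params.alpha == 2.0:
        # Ballistic limit: perfectly correlated increments = straight line.
        v = rng.standard_normal((n_tracks, 1, 2))
        inc = np.repeat(v, n_steps, axis=1)
    else:
        gx, gy = _fgn_pairs(n_steps, params.alpha / 2.0, rng, n_tracks)
        inc = np.stack([gx, gy], axis=-1)
    pos = np.zeros((n_tracks, params.n_frames, 2))
    pos[:, 1:] = np.cumsum(sigma * inc, axis=1)
    return pos


def simulate_fbm_track(params: MotionParams, seed) -> np.ndarray:
    """Single planar fBM trajectory of shape (n_frames, 2), in um."""
    return simulate_fbm_tracks(params, 1, seed)[0]


# ------------------------------------------------------------- rigid motion
def apply_rigid_motion(
    tracks_px: np.ndarray, scene: NucleusScene, n_frames: int | None = None
):
    """Move nucleus-fixed trajectories into the lab frame.

    tracks_px : (n_tracks, n_frames, 2) positions in nucleus-fixed pixels.
    Returns (lab_tracks_px, RigidTransformSeries); frame 0 is identity and
    simultaneous pairwise distances are preserved exactly (rigid motion).
    """
    tracks_px = np.asarray(tracks_px, dtype=float)
    if tracks_px.ndim == 2:
        tracks_px = tracks_px[None]
    if n_frames is None:
        n_frames = tracks_px.shape[1]
    series = scene.transform_series(n_frames)
    lab = np.empty_like(tracks_px)
    for t in range(n_frames):
        lab[:, t] = series.point_to_lab(t, tracks_px[:, t])
    return lab, series


def reflect_into_ellipse(
    xy_px: np.ndarray, center, radii, max_fold: int = 8
) -> np.ndarray:
    """Radially reflect points at the ellipse boundary (specular in the
    normalized radial coordinate), keeping every position inside the nucleus."""
    u = (np.asarray(xy_px, dtype=float) - np.asarray(center)) / np.asarray(radii)
    rho = np.linalg.norm(u, axis=-1)
    out = rho > 1.0
    for _ in range(max_fold):
        if not np.any(out):
            break
        scale = np.where(out, (2.0 - rho) / np.maximum(rho, 1e-12), 1.0)
        u = u * scale[..., None]
        rho = np.abs(np.where(out, 2.0 - rho, rho))
        out = rho > 1.0
    return u * np.asarray(radii) + np.asarray(center)


# ------------------------------------------------------------------ rendering
def _render_spots(frame: np.ndarray, xy: np.ndarray, amplitude: float, sigma: float):
    """Add isotropic Gaussian spots in-place; returns per-spot in-bounds flags."""
    h, w = frame.shape
    r = int(math.ceil(5 * sigma))
    ok = np.ones(len(xy), dtype=bool)
    for i, (x, y) in enumerate(np.atleast_2d(xy)):
        x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
        y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            ok[i] = False
            warnings.warn(
                f"spot at ({x:.1f}, {y:.1f}) extends outside the frame; "
                "rendering clipped",
                RuntimeWarning,
                stacklevel=3,
            )
        cx0, cx1 = max(x0, 0), min(x1, w)
        cy0, cy1 = max(y0, 0), min(y1, h)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        xs = np.arange(cx0, cx1)
        ys = np.arange(cy0, cy1)
        gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
        frame[cy0:cy1, cx0:cx1] += amplitude * gy[:, None] * gx[None, :]
    return ok


def _render_nucleus(scene: NucleusScene, series: RigidTransformSeries, t: int):
    h, w = scene.image_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    fixed = series.apply_to_points(t, pts)
    u = (fixed - np.asarray(scene.center)) / np.asarray(scene.radii)
    rho = np.linalg.norm(u, axis=-1).reshape(h, w)
    softness = scene.edge_softness / float(np.sqrt(np.prod(scene.radii)))
    return scene.nucleus_amplitude / (1.0 + np.exp((rho - 1.0) / max(softness, 1e-6)))


def render_frames(
    lab_tracks: dict[str, np.ndarray],
    scene: NucleusScene,
    series: RigidTransformSeries,
    seed,
    channels: tuple[str, ...] = ("nucleus", "locus", "bulk"),
):
    """Render a (T, C, Y, X) uint16 stack from lab-frame trajectories.

    ``lab_tracks`` maps probe channel name -> (n_tracks, T, 2) lab positions in
    px.  The nucleus channel is a smooth filled ellipse following the same
    rigid transforms.  Deterministic given seed.  Returns (stack, in_bounds)
    where in_bounds maps channel -> (n_tracks,) flags (False if the spot was
    ever clipped at the frame edge).
    """
    rng = np.random.default_rng(seed)
    n_frames = series.n_frames
    h, w = scene.image_shape
    stack = np.zeros((n_frames, len(channels), h, w), dtype=np.uint16)
    in_bounds = {
        ch: np.ones(len(lab_tracks[ch]), dtype=bool) for ch in lab_tracks
    }
    for t in range(n_frames):
        for ci, ch in enumerate(channels):
            img = np.full((h, w), float(scene.background_level))
            if ch == "nucleus":
                img += _render_nucleus(scene, series, t)
            elif ch in lab_tracks and len(lab_tracks[ch]):
                ok = _render_spots(
                    img, lab_tracks[ch][:, t], scene.spot_amplitude, scene.psf_sigma
                )
                in_bounds[ch] &= ok
            if scene.poisson_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if scene.noise_sd > 0:
                img = img + rng.normal(0.0, scene.noise_sd, img.shape)
            stack[t, ci] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return stack, in_bounds


# ------------------------------------------------------------------- presets
#: Locus-probe motion presets per condition (alpha, d_app in um^2/min^alpha).
#: Bulk probes always use the "bulk" preset.  "damaged-active-late" draws
#: per-track d_app from a lognormal with the stated mean and CV to produce
#: the heavy-tailed long-lag behavior of that condition.
CONDITION_PRESETS: dict[str, dict] = {
    "bulk": {"alpha": 0.8, "d_app": 2.5e-3},
    "active": {"alpha": 0.8, "d_app": 2.5e-3},
    "repressed": {"alpha": 0.8, "d_app": 1.0e-3},
    "damaged-repressed": {"alpha": 0.8, "d_app": 2.5e-3},
    "damaged-active-late": {"alpha": 0.8, "d_app": 4.0e-3, "d_cv": 0.6},
}


def _draw_d_app(preset: dict, rng: np.random.Generator) -> float:
    cv = preset.get("d_cv", 0.0)
    if cv <= 0:
        return preset["d_app"]
    s2 = math.log(1.0 + cv**2)
    mu = math.log(preset["d_app"]) - s2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(s2)))


def _place_spots(
    rng: np.random.Generator, scene: NucleusScene, n: int, min_sep: float
) -> np.ndarray:
    """Random initial positions well inside the ellipse, pairwise separated."""
    for _ in range(200):  # restart if a draw wedges itself
        pts: list[np.ndarray] = []
        for _ in range(500):
            if len(pts) == n:
                return np.array(pts)
            u = rng.uniform(-0.7, 0.7, 2)
            if np.linalg.norm(u) > 0.7:
                continue
            p = np.asarray(scene.center) + u * np.asarray(scene.radii)
            if all(np.linalg.norm(p - q) >= min_sep for q in pts):
                pts.append(p)
        if len(pts) == n:
            return np.array(pts)
    raise ParameterError(
        f"could not place {n} spots with separation {min_sep} px in the nucleus"
    )


def generate_condition_dataset(
    condition: str,
    n_cells: int,
    seed,
    *,
    n_frames: int = 40,
    frame_interval: float = 3.0,
    scene: NucleusScene | None = None,
    max_bulk_tracks: int = 5,
    min_spot_separation: float = 12.0,
    render: bool = True,
):
    """Generate one experimental condition: per-cell stacks plus ground truth.

    Each cell gets exactly one locus-probe track (motion preset set by
    ``condition``) and 1..``max_bulk_tracks`` bulk-probe tracks (bulk preset).
    Returns (ImageStackSet | None, SyntheticGroundTruth); stacks are None when
    ``render=False`` (track-table-only mode).
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}")
    if n_cells < 2:
        raise ParameterError("n_cells must be >= 2 (downstream SEM undefined)")
    base_scene = scene if scene is not None else NucleusScene()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(n_cells)

    rows = []
    transforms: dict[int, RigidTransformSeries] = {}
    motion_params: dict[tuple[int, int], MotionParams] = {}
    stacks: dict[int, np.ndarray] = {}
    locus_preset = CONDITION_PRESETS[condition]
    bulk_preset = CONDITION_PRESETS["bulk"]

    for cell_id in range(n_cells):
        css = cell_seeds[cell_id]
        rng = np.random.default_rng(css)
        cscene = replace(base_scene)
        n_bulk = int(rng.integers(1, max_bulk_tracks + 1))
        specs = [("locus", locus_preset)] + [("bulk", bulk_preset)] * n_bulk

        # per-channel initial placement (channels are imaged independently)
        starts = {
            "locus": _place_spots(rng, cscene, 1, min_spot_separation),
            "bulk": _place_spots(rng, cscene, n_bulk, min_spot_separation),
        }
        fixed_px = {}
        track_id = 0
        per_channel_tracks: dict[str, list[np.ndarray]] = {"locus": [], "bulk": []}
        chan_counter = {"locus": 0, "bulk": 0}
        for probe, preset in specs:
            mp = MotionParams(
                alpha=preset["alpha"],
                d_app=_draw_d_app(preset, rng),
                frame_interval=frame_interval,
                n_frames=n_frames,
            )
            traj_um = simulate_fbm_tracks(mp, 1, css.spawn(1)[0])[0]
            start = starts[probe][chan_counter[probe]]
            chan_counter[probe] += 1
            traj_px = start + traj_um / cscene.pixel_size
            traj_px = reflect_into_ellipse(traj_px, cscene.center, cscene.radii)
            per_channel_tracks[probe].append(traj_px)
            motion_params[(cell_id, track_id)] = mp
            fixed_px[track_id] = (probe, traj_px)
            track_id += 1

        all_fixed = np.stack([v[1] for v in fixed_px.values()])
        lab, series = apply_rigid_motion(all_fixed, cscene, n_frames)
        transforms[cell_id] = series

        in_bounds = {"locus": None, "bulk": None}
        if render:
            lab_by_channel = {
                "locus": np.stack(
                    [lab[i] for i, (p, _) in fixed_px.items() if p == "locus"]
                ),
                "bulk": np.stack(
                    [lab[i] for i, (p, _) in fixed_px.items() if p == "bulk"]
                ),
            }
            stack, in_bounds = render_frames(
                lab_by_channel, cscene, series, css.spawn(1)[0]
            )
            stacks[cell_id] = stack

        chan_seen = {"locus": 0, "bulk": 0}
        for tid, (probe, traj_px) in fixed_px.items():
            idx_in_channel = chan_seen[probe]
            chan_seen[probe] += 1
            ok = (
                bool(in_bounds[probe][idx_in_channel])
                if in_bounds[probe] is not None
                else True
            )
            for t in range(n_frames):
                rows.append(
                    {
                        "cell_id": cell_id,
                        "track_id": tid,
                        "probe": probe,
                        "condition": condition,
                        "frame": t,
                        "x_px": traj_px[t, 0],
                        "y_px": traj_px[t, 1],
                        "x_um": traj_px[t, 0] * cscene.pixel_size,
                        "y_um": traj_px[t, 1] * cscene.pixel_size,
                        "lab_x_px": lab[tid, t, 0],
                        "lab_y_px": lab[tid, t, 1],
                        "in_bounds": ok,
                    }
                )

    truth = SyntheticGroundTruth(
        tracks=pd.DataFrame(rows),
        transforms=transforms,
        motion_params=motion_params,
        condition=condition,
        scene=base_scene,
        n_frames=n_frames,
    )
    images = (
        ImageStackSet(
            stacks=stacks,
            channels=("nucleus", "locus", "bulk"),
            pixel_size=base_scene.pixel_size,
            frame_interval=frame_interval,
        )
        if render
        else None
    )
    return images, truth


# ------------------------------------------------------------------ dosimetry
def compute_fluence(
    irradiance: float, duration: float, target_area: float | None = None
) -> FluenceResult:
    """Photoactivation dosimetry: fluence = irradiance * duration (J/m^2);
    if a target area (m^2) is given, also the energy delivered to it (J)."""
    if irradiance < 0 or duration < 0:
        raise ParameterError("irradiance and duration must be >= 0")
    if target_area is not None and target_area < 0:
        raise ParameterError("target_area must be >= 0")
    fluence = irradiance * duration
    energy = None if target_area is None else fluence * target_area
    return FluenceResult(fluence_j_m2=fluence, energy_j=energy)
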