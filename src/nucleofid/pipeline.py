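"""End-to-end orchestration: synth -> register -> detect -> link -> msd.

The pipeline generates (or loads) per-cell multi-channel movies, estimates
rigid nuclear motion on the counterstain channel, detects probe spots on the
raw frames and corrects their coordinates through the estimated transforms
(coordinate-level correction avoids resampling noise), links detections into
persistent full-duration tracks, and computes outlier-screened per-cell and
ensemble MSD curves, power-law fits and per-lag group comparisons.  Every run
records a manifest with seeds, parameters and per-stage counts so a config
reproduces its outputs deterministically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as _detect
from . import io as _io
from . import link as _link
from . import msd as _msd
from . import register as _register
from . import synth as _synth
from .errors import EmptyResultError, ParameterError
from .link import TrackSet

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_against_truth"]


@dataclass
class PipelineConfig:
    """Serializable description of one synthetic study run."""

    conditions: list = field(
        default_factory=lambda: ["bulk", "repressed", "damaged-repressed"]
    )
    n_cells: int = 10
    n_frames: int = 30
    frame_interval: float = 3.0  # minutes
    seed: int = 7
    # scene overrides (NucleusScene field name -> value)
    scene: dict = field(default_factory=dict)
    threshold_k: float = 4.0
    psf_sigma: float | None = None  # default: scene psf_sigma
    max_link_distance: float = 5.0  # px, multi-spot (bulk) channels
    # the locus channel holds exactly one spot per nucleus, so its gate only
    # rejects artifacts; sized to the largest per-frame steps of the most
    # mobile (damage) condition at 3-min intervals
    max_link_distance_locus: float = 8.0  # px
    max_lag_fraction: float = 1 / 3
    alpha_level: float = 0.05
    compare: list = field(
        default_factory=lambda: [
            ["repressed", "bulk"],
            ["damaged-repressed", "bulk"],
        ]
    )
    out_dir: str | None = None
    save_images: bool = False

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def make_scene(self) -> _synth.NucleusScene:
        return _synth.NucleusScene(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in self.scene.items()
        })


@dataclass
class PipelineResult:
    trackset: TrackSet
    curves: dict  # (condition, probe) -> {"ensemble", "cells", "excluded"}
    fits: dict  # (condition, probe) -> PowerLawFit
    comparisons: dict  # (label_a, label_b) -> ComparisonResult
    manifest: dict
    truths: dict  # condition -> SyntheticGroundTruth
    transforms_est: dict  # (condition, cell_id) -> RigidTransformSeries


def analyze_cell_stack(
    stack: np.ndarray,
    channels: tuple,
    config: PipelineConfig,
    scene: _synth.NucleusScene,
):
    """Register one cell's movie and return per-channel persistent candidates.

    Returns (per-probe candidate track lists in reference-frame px, estimated
    RigidTransformSeries).
    """
    nuc_idx = channels.index("nucleus")
    series = _register.estimate_transforms(stack[:, nuc_idx].astype(float))
    psf_sigma = config.psf_sigma if config.psf_sigma is not None else scene.psf_sigma
    n_frames = stack.shape[0]
    candidates = {}
    for ch in channels:
        if ch == "nucleus":
            continue
        ci = channels.index(ch)
        per_frame = []
        for t in range(n_frames):
            frame = stack[t, ci].astype(float)
            calib = _detect.calibrate_noise(frame, threshold_k=config.threshold_k)
            if ch == "locus":
                mask = _detect.nucleus_mask(stack[t, nuc_idx].astype(float))
                dets = [
                    _detect.detect_brightest(
                        frame, calib, psf_sigma, mask, frame_index=t, channel=ch
                    )
                ]
            else:
                dets = _detect.detect_particles(
                    frame, calib, psf_sigma, frame_index=t, channel=ch
                )
            corrected = []
            for d in dets:
                ref_xy = series.apply_to_points(t, np.array([[d.x, d.y]]))[0]
                corrected.append((float(ref_xy[0]), float(ref_xy[1])))
            per_frame.append(corrected)
        gate = (
            config.max_link_distance_locus
            if ch == "locus"
            else config.max_link_distance
        )
        candidates[ch] = _link.link_frames(per_frame, gate)
    return candidates, series


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic study described by ``config``."""
    for cond in config.conditions:
        if cond not in _synth.CONDITIONS:
            raise ParameterError(f"unknown condition {cond!r}")
    scene = config.make_scene()
    root_ss = np.random.SeedSequence(config.seed)
    cond_seeds = {c: s for c, s in zip(config.conditions, root_ss.spawn(len(config.conditions)))}

    all_tracks = []
    truths = {}
    transforms_est = {}
    counts = {}
    track_counter = 0
    for cond in config.conditions:
        images, truth = _synth.generate_condition_dataset(
            cond,
            config.n_cells,
            cond_seeds[cond],
            n_frames=config.n_frames,
            frame_interval=config.frame_interval,
            scene=scene,
        )
        truths[cond] = truth
        n_det = 0
        n_candidates = 0
        n_persistent = 0
        for cell_id in images.cell_ids:
            candidates, series = analyze_cell_stack(
                images.stacks[cell_id], images.channels, config, scene
            )
            transforms_est[(cond, cell_id)] = series
            for probe, cands in candidates.items():
                n_candidates += len(cands)
                n_det += sum(len(c.xy) for c in cands)
                ts = _link.filter_persistent(
                    cands,
                    config.n_frames,
                    cell_id=cell_id,
                    probe=probe,
                    condition=cond,
                    frame_interval=config.frame_interval,
                    pixel_size=scene.pixel_size,
                    allow_empty=(probe == "bulk"),
                )
                for tr in ts.tracks:
                    tr.track_id = track_counter
                    track_counter += 1
                    all_tracks.append(tr)
                n_persistent += len(ts)
        counts[cond] = {
            "cells": config.n_cells,
            "detections": n_det,
            "candidate_tracks": n_candidates,
            "persistent_tracks": n_persistent,
        }

    if not all_tracks:
        raise EmptyResultError("pipeline", "no persistent tracks in any condition")
    trackset = TrackSet(
        all_tracks, config.n_frames, config.frame_interval, scene.pixel_size
    )

    curves, fits, outlier_counts = analyze_trackset(
        trackset, max_lag_fraction=config.max_lag_fraction
    )
    for cond, c in counts.items():
        c["outliers_removed"] = outlier_counts.get(cond, 0)

    comparisons = {}
    for pair in config.compare:
        a, b = pair
        key_a = _resolve_group(curves, a)
        key_b = _resolve_group(curves, b)
        comparisons[(a, b)] = _msd.compare_msd(
            curves[key_a]["cells"], curves[key_b]["cells"], config.alpha_level
        )

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "counts": counts,
        "n_tracks": len(trackset),
        "fits": {
            f"{cond}/{probe}": {
                "alpha_hat": f.alpha_hat,
                "d_hat": f.d_hat,
                "r_squared": f.r_squared,
            }
            for (cond, probe), f in fits.items()
        },
    }

    result = PipelineResult(
        trackset=trackset,
        curves=curves,
        fits=fits,
        comparisons=comparisons,
        manifest=manifest,
        truths=truths,
        transforms_est=transforms_est,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _resolve_group(curves: dict, label: str):
    """A comparison label is a condition (locus probe) or 'bulk' (bulk probe)."""
    if label == "bulk" and ("bulk", "bulk") in curves:
        return ("bulk", "bulk")
    for (cond, probe) in curves:
        if cond == label and probe == "locus":
            return (cond, probe)
    raise ParameterError(f"no analyzed group for label {label!r}")


def analyze_trackset(trackset: TrackSet, max_lag_fraction: float = 1 / 3):
    """Outlier-screen, average and fit every (condition, probe) group."""
    curves = {}
    fits = {}
    outlier_counts = {}
    groups = sorted({(t.condition, t.probe) for t in trackset.tracks})
    for cond, probe in groups:
        sub = trackset.subset(probe=probe, condition=cond)
        track_curves = [
            _msd.track_msd(t, max_lag_fraction=max_lag_fraction) for t in sub.tracks
        ]
        included, excluded = _msd.remove_outliers(track_curves)
        if not included:
            raise EmptyResultError("msd", f"all tracks excluded for {cond}/{probe}")
        ens = _msd.ensemble_msd(included)
        cells = _msd.cell_average(included)
        curves[(cond, probe)] = {
            "ensemble": ens,
            "cells": cells,
            "excluded": [c.track_id for c in excluded],
        }
        outlier_counts[cond] = outlier_counts.get(cond, 0) + len(excluded)
        fits[(cond, probe)] = _msd.fit_power_law(ens)
    return curves, fits, outlier_counts


def _write_outputs(result: PipelineResult, config: PipelineConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.trackset.to_dataframe().to_csv(out / "tracks.csv", index=False)
    _io.curves_to_dataframe(result.curves).to_csv(out / "msd_curves.csv", index=False)
    comp_rows = []
    for (a, b), comp in result.comparisons.items():
        df = comp.to_dataframe()
        df.insert(0, "group_a", a)
        df.insert(1, "group_b", b)
        comp_rows.append(df)
    if comp_rows:
        pd.concat(comp_rows).to_csv(out / "comparisons.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    config.to_yaml(out / "config.yaml")
    try:
        plot_msd_curves(result.curves, out / "msd_curves.png")
    except Exception:  # plotting must never break an analysis run
        pass


def plot_msd_curves(curves: dict, path):
    """Log-log ensemble MSD plot with SEM error bars, one line per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (cond, probe), entry in sorted(curves.items()):
        ens = entry["ensemble"]
        ax.errorbar(
            ens.lags, ens.values, yerr=ens.sem, label=f"{cond}/{probe}", capsize=2
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("lag time (min)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ------------------------------------------------------------------ validation
def validate_against_truth(
    result: PipelineResult, truth, match_radius_px: float = 2.0
) -> dict:
    """Recovery report of the pipeline against synthetic ground truth.

    Reports detection recall/precision (by position matching in the reference
    frame), registration residuals (angle error and the displacement error of
    the estimated transform at the nucleus center), and alpha / d_app
    recovery per probe group.
    """
    cond = truth.condition
    cells_truth = set(truth.cell_ids)
    cells_res = {
        cell for (c, cell) in result.transforms_est if c == cond
    }
    if not cells_res:
        raise ParameterError(f"result contains no cells for condition {cond!r}")
    if cells_res - cells_truth:
        raise ParameterError("result/truth cell mismatch")

    # registration residuals
    ang_err = []
    disp_err = []
    for cell in sorted(cells_res):
        est = result.transforms_est[(cond, cell)]
        true = truth.transforms[cell]
        c = np.asarray(true.center)
        for t in range(true.n_frames):
            ang_err.append(abs(est.theta_deg[t] - true.theta_deg[t]))
            disp_err.append(
                float(
                    np.linalg.norm(
                        est.point_to_lab(t, c[None]) - true.point_to_lab(t, c[None])
                    )
                )
            )

    # track recovery: match persistent tracks to truth by median position
    sub = result.trackset.subset(condition=cond)
    tdf = truth.tracks
    px = truth.scene.pixel_size
    matched = 0
    pos_err = []
    for tr in sub.tracks:
        cand = tdf[(tdf["cell_id"] == _track_cell(tr)) & (tdf["probe"] == tr.probe)]
        best = None
        for tid, g in cand.groupby("track_id"):
            g = g.sort_values("frame")
            true_xy = g[["x_px", "y_px"]].to_numpy()
            est_xy = tr.xy_um / px
            n = min(len(true_xy), len(est_xy))
            rms = float(
                np.sqrt(np.mean(np.sum((true_xy[:n] - est_xy[:n]) ** 2, axis=1)))
            )
            if best is None or rms < best:
                best = rms
        if best is not None and best <= match_radius_px:
            matched += 1
            pos_err.append(best)
    n_truth_persistent = tdf.groupby(["cell_id", "track_id"]).ngroups
    recall = matched / n_truth_persistent if n_truth_persistent else float("nan")
    precision = matched / len(sub.tracks) if len(sub.tracks) else float("nan")

    # parameter recovery per probe group
    recovery = {}
    for probe in ("locus", "bulk"):
        key = (cond, probe)
        if key not in result.curves:
            continue
        fit = result.fits[key]
        mps = [
            mp
            for (cell, tid), mp in truth.motion_params.items()
            if truth.tracks[
                (truth.tracks["cell_id"] == cell)
                & (truth.tracks["track_id"] == tid)
            ]["probe"].iloc[0]
            == probe
        ]
        true_alpha = float(np.mean([m.alpha for m in mps]))
        true_d = float(np.mean([m.d_app for m in mps]))
        recovery[probe] = {
            "alpha_hat": fit.alpha_hat,
            "alpha_true": true_alpha,
            "alpha_error": fit.alpha_hat - true_alpha,
            "d_hat": fit.d_hat,
            "d_true_mean": true_d,
            "d_rel_error": fit.d_hat / true_d - 1.0,
        }

    return {
        "condition": cond,
        "registration": {
            "max_angle_error_deg": float(np.max(ang_err)),
            "max_center_displacement_error_px": float(np.max(disp_err)),
            "rms_center_displacement_error_px": float(
                np.sqrt(np.mean(np.square(disp_err)))
            ),
        },
        "tracking": {
            "recall": recall,
            "precision": precision,
            "rms_position_error_px": float(np.mean(pos_err)) if pos_err else None,
        },
        "recovery": recovery,
    }


def _track_cell(track) -> int:
    return track.cell_id
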