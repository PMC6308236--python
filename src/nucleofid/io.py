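"""Reading and writing of the pipeline's on-disk formats.

Stacks are multi-page 16-bit TIFFs (one file per channel per cell), tabular
outputs are CSV, transforms follow the (frame, dx_px, dy_px, theta_deg)
schema, and configurations are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synth import ImageStackSet, SyntheticGroundTruth
from .transforms import RigidTransformSeries

TRUTH_COLUMNS = [
    "cell_id",
    "track_id",
    "probe",
    "condition",
    "frame",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
]


def save_stack_set(images: ImageStackSet, out_dir) -> list[Path]:
    """Write one multi-page TIFF per channel per cell: cell{ID}_{channel}.tif."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cell_id, stack in images.stacks.items():
        for ci, ch in enumerate(images.channels):
            path = out / f"cell{cell_id:03d}_{ch}.tif"
            tifffile.imwrite(
                path, stack[:, ci].astype(np.uint16), photometric="minisblack"
            )
            written.append(path)
    return written


def load_stack_set(
    in_dir, channels=("nucleus", "locus", "bulk"), pixel_size=0.1, frame_interval=3.0
) -> ImageStackSet:
    """Load cell{ID}_{channel}.tif files written by :func:`save_stack_set`."""
    in_dir = Path(in_dir)
    cells: dict[int, dict[str, np.ndarray]] = {}
    for path in sorted(in_dir.glob("cell*_*.tif")):
        stem = path.stem  # cell{ID}_{channel}
        cid_part, ch = stem.split("_", 1)
        cid = int(cid_part.removeprefix("cell"))
        cells.setdefault(cid, {})[ch] = tifffile.imread(path)
    stacks = {}
    for cid, by_ch in cells.items():
        planes = [by_ch[ch] for ch in channels if ch in by_ch]
        stacks[cid] = np.stack(planes, axis=1)
    present = tuple(ch for ch in channels if any(ch in v for v in cells.values()))
    return ImageStackSet(
        stacks=stacks,
        channels=present,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )


def save_truth(truth: SyntheticGroundTruth, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.tracks.to_csv(out / "ground_truth_tracks.csv", index=False)
    rows = []
    for cell_id, series in truth.transforms.items():
        df = series.to_dataframe()
        df.insert(0, "cell_id", cell_id)
        rows.append(df)
    pd.concat(rows).to_csv(out / "ground_truth_transforms.csv", index=False)
    scene = truth.scene
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "condition": truth.condition,
                "n_frames": truth.n_frames,
                "center": list(scene.center),
                "radii": list(scene.radii),
                "psf_sigma": scene.psf_sigma,
                "spot_amplitude": scene.spot_amplitude,
                "background_level": scene.background_level,
                "read_noise_sd": scene.noise_sd,
                "poisson_noise": scene.poisson_noise,
                "pixel_size": scene.pixel_size,
                "image_shape": list(scene.image_shape),
            },
            fh,
        )


def save_transforms(series: RigidTransformSeries, path):
    series.to_dataframe().to_csv(path, index=False)


def load_transforms(path, center=(0.0, 0.0)) -> RigidTransformSeries:
    return RigidTransformSeries.from_dataframe(pd.read_csv(path), center)


def detections_to_dataframe(dets) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": d.frame,
                "x_px": d.x,
                "y_px": d.y,
                "intensity": d.intensity,
                "snr": d.snr,
                "channel": d.channel,
            }
            for d in dets
        ]
    )


def curves_to_dataframe(curves_by_group: dict) -> pd.DataFrame:
    """Flatten {(condition, probe): {"ensemble": curve, "cells": [curves]}}."""
    rows = []
    for (condition, probe), entry in curves_by_group.items():
        ens = entry["ensemble"]
        for i, lag in enumerate(ens.lags):
            rows.append(
                {
                    "condition": condition,
                    "probe": probe,
                    "level": "ensemble",
                    "cell_id": "",
                    "lag_min": lag,
                    "msd_um2": ens.values[i],
                    "sem": ens.sem[i] if ens.sem is not None else np.nan,
                    "n": ens.n_cells,
                }
            )
        for c in entry.get("cells", []):
            for i, lag in enumerate(c.lags):
                rows.append(
                    {
                        "condition": condition,
                        "probe": probe,
                        "level": "cell",
                        "cell_id": c.cell_id,
                        "lag_min": lag,
                        "msd_um2": c.values[i],
                        "sem": np.nan,
                        "n": 1,
                    }
                )
    return pd.DataFrame(rows)
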