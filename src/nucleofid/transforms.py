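"""Rigid-body transform series shared by the generator and the registration stage.

Coordinates follow the array convention used throughout the package:
``x`` is the column index, ``y`` the row index (both in pixels, sub-pixel
valued), and angles are measured in degrees from +x toward +y.  Because +y
points down the screen this is a clockwise rotation when the image is
displayed, but the convention is self-consistent between the synthetic
generator and the registration stage, which is all that matters for the
physics: only relative angles enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

TRANSFORM_COLUMNS = ("frame", "dx_px", "dy_px", "theta_deg")


def _rot(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransformSeries:
    """Per-frame rigid nuclear motion: translation plus rotation about a center.

    At frame ``t`` the nucleus (and everything bound to it) sits rotated by
    ``theta_deg[t]`` about ``center`` and translated by ``(dx[t], dy[t])``
    relative to the reference frame, i.e. the forward (nucleus-fixed ->
    lab-frame) map is::

        p_lab = R(theta_t) @ (p - center) + center + (dx_t, dy_t)

    ``apply_to_points`` inverts this, mapping lab-frame coordinates back into
    the reference (nucleus-fixed) frame so that only intranuclear motion
    remains.
    """

    dx: np.ndarray
    dy: np.ndarray
    theta_deg: np.ndarray
    center: tuple[float, float]
    reference_frame_index: int = 0

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        if not (self.dx.shape == self.dy.shape == self.theta_deg.shape):
            raise ParameterError("dx, dy, theta_deg must have equal length")
        i = self.reference_frame_index
        if not (
            abs(self.dx[i]) < 1e-9
            and abs(self.dy[i]) < 1e-9
            and abs(self.theta_deg[i]) < 1e-9
        ):
            raise ParameterError("transform at the reference frame must be identity")

    @property
    def n_frames(self) -> int:
        return self.dx.size

    @classmethod
    def identity(cls, n_frames: int, center=(0.0, 0.0)) -> "RigidTransformSeries":
        z = np.zeros(n_frames)
        return cls(z, z.copy(), z.copy(), tuple(center))

    # ------------------------------------------------------------------ points
    def point_to_lab(self, frame: int, xy: np.ndarray) -> np.ndarray:
        """Map nucleus-fixed coordinates to lab-frame coordinates at ``frame``."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        self._check_frame(frame)
        c = np.asarray(self.center)
        d = np.array([self.dx[frame], self.dy[frame]])
        return (xy - c) @ _rot(self.theta_deg[frame]).T + c + d

    def apply_to_points(self, frame: int, xy_lab: np.ndarray) -> np.ndarray:
        """Map lab-frame coordinates at ``frame`` into the reference frame."""
        xy_lab = np.atleast_2d(np.asarray(xy_lab, dtype=float))
        self._check_frame(frame)
        c = np.asarray(self.center)
        d = np.array([self.dx[frame], self.dy[frame]])
        return (xy_lab - c - d) @ _rot(-self.theta_deg[frame]).T + c

    def _check_frame(self, frame: int):
        if not (0 <= frame < self.n_frames):
            raise ParameterError(
                f"frame {frame} outside transform series of length {self.n_frames}"
            )

    # ------------------------------------------------------------------ matrix
    def forward_matrix(self, frame: int) -> np.ndarray:
        """3x3 homogeneous matrix of the nucleus-fixed -> lab map in (x, y)."""
        self._check_frame(frame)
        R = _rot(self.theta_deg[frame])
        c = np.asarray(self.center)
        d = np.array([self.dx[frame], self.dy[frame]])
        m = np.eye(3)
        m[:2, :2] = R
        m[:2, 2] = c + d - R @ c
        return m

    # --------------------------------------------------------------------- io
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "dx_px": self.dx,
                "dy_px": self.dy,
                "theta_deg": self.theta_deg,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, center=(0.0, 0.0)) -> "RigidTransformSeries":
        df = df.sort_values("frame")
        return cls(
            df["dx_px"].to_numpy(),
            df["dy_px"].to_numpy(),
            df["theta_deg"].to_numpy(),
            tuple(center),
        )
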