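"""Rigid-body nuclear registration.

Estimates and removes per-frame nuclear translation and rotation from the
counterstain channel so that only intranuclear particle motion remains.
Translation is estimated by phase correlation with sub-pixel upsampling;
rotation by correlating polar resamplings of the two images about the nucleus
centroid; the two estimates are refined alternately.  All frames are
registered against a fixed reference frame (frame 0 by default) to avoid
error accumulation from a running reference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp, warp_polar

from .errors import ParameterError, RegistrationError
from .transforms import RigidTransformSeries, _rot

__all__ = [
    "estimate_translation",
    "estimate_rotation",
    "estimate_transforms",
    "align_stack",
    "transform_tracks",
    "nucleus_centroid",
]


def _check_pair(frame: np.ndarray, reference: np.ndarray):
    if frame.shape != reference.shape:
        raise RegistrationError(
            f"shape mismatch: frame {frame.shape} vs reference {reference.shape}"
        )
    if float(np.std(frame)) == 0.0 or float(np.std(reference)) == 0.0:
        raise RegistrationError("blank (zero-variance) frame cannot be registered")


def nucleus_centroid(image: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (x, y) of the background-subtracted image."""
    img = np.asarray(image, dtype=float)
    w = np.clip(img - np.median(img), 0, None)
    if w.sum() == 0:
        raise RegistrationError("cannot compute centroid of a flat image")
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (float((w * xx).sum() / w.sum()), float((w * yy).sum() / w.sum()))


def estimate_translation(
    frame: np.ndarray, reference: np.ndarray, upsample_factor: int = 50
) -> tuple[float, float]:
    """Sub-pixel shift (dx, dy) such that frame ~= reference translated by it."""
    _check_pair(frame, reference)
    shift, _, _ = phase_cross_correlation(
        reference.astype(float),
        frame.astype(float),
        upsample_factor=upsample_factor,
        normalization=None,
    )
    # phase_cross_correlation returns (row, col) shift registering frame onto
    # reference; the motion that produced the frame is the opposite sign.
    return (float(-shift[1]), float(-shift[0]))


def estimate_rotation(
    frame: np.ndarray,
    reference: np.ndarray,
    center: tuple[float, float],
    upsample_factor: int = 50,
    angular_samples: int = 720,
    symmetry_tol: float = 1e-3,
    prior: float | None = None,
) -> float:
    """Rotation angle (degrees, +x toward +y) of ``frame`` relative to
    ``reference`` about ``center``; translation must already be removed.

    Rotationally symmetric content (a perfect disk) makes the angle
    unidentifiable: a warning is raised and 0 returned.  Content with
    two-fold symmetry (an ellipse-like nucleus) leaves a half-turn alias;
    if ``prior`` (degrees) is given the alias closest to it wins (rigid
    nuclear rotation is continuous in time, so the previous frame's angle is
    a valid prior), otherwise both aliases are scored against the reference
    and ties resolve to the smaller rotation.
    """
    _check_pair(frame, reference)
    h, w = reference.shape
    radius = min(center[0], center[1], w - 1 - center[0], h - 1 - center[1])
    radius = max(radius, 4.0)
    kw = dict(
        center=(center[1], center[0]),  # warp_polar takes (row, col)
        radius=radius,
        output_shape=(angular_samples, int(radius)),
    )
    # inner radii carry little angular information and large resampling error
    inner = int(radius) // 4
    pol_ref = warp_polar(reference.astype(float), **kw)[:, inner:]
    pol_frm = warp_polar(frame.astype(float), **kw)[:, inner:]
    # keep only radii with real angular structure (the nuclear rim); pure
    # background columns contribute noise but no rotation signal
    col_var = np.var(pol_ref, axis=0)
    keep = col_var > 0.1 * col_var.max()
    if keep.sum() >= 4:
        pol_ref = pol_ref[:, keep]
        pol_frm = pol_frm[:, keep]
    angular_power = float(np.mean(np.var(pol_ref, axis=0)))
    total_power = float(np.var(pol_ref))
    if total_power == 0 or angular_power / total_power < symmetry_tol:
        warnings.warn(
            "rotationally symmetric content: rotation is ambiguous, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    shift, _, _ = phase_cross_correlation(
        pol_ref, pol_frm, upsample_factor=upsample_factor, normalization=None
    )
    angle = -float(shift[0]) * (360.0 / angular_samples)
    # wrap to (-180, 180], then resolve the half-turn alias by direct scoring
    angle = (angle + 180.0) % 360.0 - 180.0
    alias = angle - 180.0 if angle > 0 else angle + 180.0
    if prior is not None:
        angle = min(
            (angle, alias),
            key=lambda a: abs((a - prior + 180.0) % 360.0 - 180.0),
        )
    else:
        candidates = sorted({angle, alias}, key=abs)
        if len(candidates) == 2:
            scores = [_rotation_score(frame, reference, center, a) for a in candidates]
            # prefer the half-turn alias only when it is clearly better: on
            # two-fold-symmetric content the scores tie up to noise
            if scores[1] > scores[0] + 0.01:
                angle = candidates[1]
            else:
                angle = candidates[0]
        else:
            angle = candidates[0]
    # sub-degree polish: principal axes of the second central moments rotate
    # exactly with the image and average the noise over every pixel
    delta = _moment_orientation(frame) - _moment_orientation(reference) - angle
    delta = (delta + 90.0) % 180.0 - 90.0
    if abs(delta) < 5.0:
        angle += delta
    return angle


def _moment_orientation(image: np.ndarray) -> float:
    """Principal-axis orientation (degrees, x toward y) of the bright content."""
    arr = np.asarray(image, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    img = np.clip(arr - med - 3.0 * 1.4826 * mad, 0, None)
    tot = img.sum()
    if tot <= 0:
        return 0.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    cx = (img * xx).sum() / tot
    cy = (img * yy).sum() / tot
    mxx = (img * (xx - cx) ** 2).sum() / tot
    myy = (img * (yy - cy) ** 2).sum() / tot
    mxy = (img * (xx - cx) * (yy - cy)).sum() / tot
    return float(np.degrees(0.5 * np.arctan2(2 * mxy, mxx - myy)))


def _rotation_score(frame, reference, center, angle_deg) -> float:
    """Normalized correlation of ``frame`` unrotated by ``angle_deg`` with ref."""
    series = RigidTransformSeries(
        np.array([0.0, 0.0]), np.array([0.0, 0.0]), np.array([0.0, angle_deg]), center
    )
    unrot = _apply_inverse_to_image(frame, series, 1, order=1)
    a = unrot - unrot.mean()
    b = reference - reference.mean()
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _apply_inverse_to_image(
    image: np.ndarray, series: RigidTransformSeries, t: int, order: int = 3
) -> np.ndarray:
    """Resample frame ``t`` into the reference frame (undo the rigid motion)."""
    m = series.forward_matrix(t)
    return warp(
        image.astype(float),
        inverse_map=AffineTransform(matrix=m),
        order=order,
        mode="constant",
        cval=float(np.median(image)),
        preserve_range=True,
    )


def estimate_transforms(
    nucleus_stack: np.ndarray,
    reference_frame_index: int = 0,
    n_refine: int = 2,
    center: tuple[float, float] | None = None,
    upsample_factor: int = 50,
    smooth_sigma: float = 2.0,
) -> RigidTransformSeries:
    """Estimate per-frame rigid motion of a (T, Y, X) nucleus-channel stack.

    Every frame is registered directly against the reference frame: first the
    translation (phase correlation), then the rotation about the reference
    nucleus centroid (polar correlation), alternating ``n_refine`` times.
    Frames are Gaussian-smoothed (``smooth_sigma`` px) before correlation to
    suppress read noise; the same blur on both images leaves the estimated
    shift and angle unbiased.  The half-turn rotation alias on near-symmetric
    nuclei is resolved by temporal continuity with the previous frame.
    """
    stack = np.asarray(nucleus_stack, dtype=float)
    if stack.ndim != 3:
        raise ParameterError("nucleus_stack must be (T, Y, X)")
    if smooth_sigma > 0:
        stack = np.stack([ndi.gaussian_filter(f, smooth_sigma) for f in stack])
    ref = stack[reference_frame_index]
    if center is None:
        center = nucleus_centroid(ref)
    n = stack.shape[0]
    dx = np.zeros(n)
    dy = np.zeros(n)
    th = np.zeros(n)
    order = [reference_frame_index] + sorted(
        set(range(n)) - {reference_frame_index},
        key=lambda t: abs(t - reference_frame_index),
    )
    prev_theta: dict[int, float] = {reference_frame_index: 0.0}
    for t in order:
        if t == reference_frame_index:
            continue
        frm = stack[t]
        neighbor = t - 1 if t > reference_frame_index else t + 1
        prior0 = prev_theta.get(neighbor, 0.0)
        d = np.array(estimate_translation(frm, ref, upsample_factor))
        theta = 0.0
        for _ in range(max(1, n_refine)):
            trial = RigidTransformSeries(
                np.array([0.0, d[0]]),
                np.array([0.0, d[1]]),
                np.array([0.0, theta]),
                center,
            )
            aligned = _apply_inverse_to_image(frm, trial, 1)
            theta += estimate_rotation(
                aligned, ref, center, upsample_factor, prior=prior0 - theta
            )
            trial = RigidTransformSeries(
                np.array([0.0, d[0]]),
                np.array([0.0, d[1]]),
                np.array([0.0, theta]),
                center,
            )
            aligned = _apply_inverse_to_image(frm, trial, 1)
            resid = np.array(estimate_translation(aligned, ref, upsample_factor))
            # residual measured in reference space; map through the rotation
            d = d + _rot(theta) @ resid
        dx[t], dy[t], th[t] = d[0], d[1], theta
        prev_theta[t] = theta
    return RigidTransformSeries(dx, dy, th, center, reference_frame_index)


def align_stack(
    stack: np.ndarray, transforms: RigidTransformSeries, order: int = 3
) -> np.ndarray:
    """Resample a (T, Y, X) or (T, C, Y, X) stack into the reference frame.

    All channels of a frame receive the same transform.
    """
    arr = np.asarray(stack, dtype=float)
    multi = arr.ndim == 4
    if not multi and arr.ndim != 3:
        raise ParameterError("stack must be (T, Y, X) or (T, C, Y, X)")
    if arr.shape[0] != transforms.n_frames:
        raise RegistrationError(
            f"stack has {arr.shape[0]} frames but transforms cover "
            f"{transforms.n_frames}"
        )
    out = np.empty_like(arr)
    for t in range(arr.shape[0]):
        if multi:
            for c in range(arr.shape[1]):
                out[t, c] = _apply_inverse_to_image(arr[t, c], transforms, t, order)
        else:
            out[t] = _apply_inverse_to_image(arr[t], transforms, t, order)
    return out


def transform_tracks(
    tracks_lab_px: np.ndarray, transforms: RigidTransformSeries
) -> np.ndarray:
    """Map lab-frame trajectories (..., n_frames, 2) into the reference frame.

    Coordinate-level equivalent of ``align_stack``: preferred for quantitative
    work because it introduces no resampling noise.
    """
    arr = np.asarray(tracks_lab_px, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.shape[1] != transforms.n_frames:
        raise ParameterError(
            f"tracks have {arr.shape[1]} frames but transforms cover "
            f"{transforms.n_frames}"
        )
    out = np.empty_like(arr)
    for t in range(arr.shape[1]):
        out[:, t] = transforms.apply_to_points(t, arr[:, t])
    return out[0] if single else out
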