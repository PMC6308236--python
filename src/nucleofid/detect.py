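"""Statistical spot detection with background-noise calibration.

The detector first calibrates the background (robust mean and SD of the
non-spot pixels), then band-pass filters the frame with a difference of
Gaussians matched to the point-spread function, takes local maxima as
candidates, refines each candidate to sub-pixel precision with an iterated
Gaussian-weighted centroid, and finally keeps candidates whose estimated
spot amplitude exceeds ``threshold_k`` background standard deviations.  The
reported ``snr`` is that amplitude estimate divided by the background SD, so
the detection rule is exactly ``snr >= threshold_k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians, gaussian, threshold_otsu

from .errors import DetectionError, ParameterError

__all__ = [
    "NoiseCalibration",
    "Detection",
    "calibrate_noise",
    "detect_particles",
    "detect_brightest",
    "nucleus_mask",
]


@dataclass(frozen=True)
class NoiseCalibration:
    """Background statistics of one frame plus the detection multiplier.

    The detection threshold in intensity units is
    ``background_mean + threshold_k * background_sd``.
    """

    background_mean: float
    background_sd: float
    threshold_k: float = 4.0
    background_mask_source: str = "otsu-complement"

    def __post_init__(self):
        if self.background_sd <= 0:
            raise DetectionError("background SD must be > 0 (degenerate frame?)")

    @property
    def threshold(self) -> float:
        return self.background_mean + self.threshold_k * self.background_sd


@dataclass(frozen=True)
class Detection:
    """One detected spot: sub-pixel position, integrated intensity, SNR."""

    frame: int
    x: float
    y: float
    intensity: float  # background-subtracted integrated counts
    snr: float  # amplitude estimate / background SD
    channel: str = ""


def _sigma_clipped_stats(values: np.ndarray, n_sd: float = 3.0, iters: int = 5):
    v = np.asarray(values, dtype=float).ravel()
    for _ in range(iters):
        m, s = v.mean(), v.std()
        if s == 0:
            break
        keep = np.abs(v - m) <= n_sd * s
        if keep.all():
            break
        v = v[keep]
    return float(v.mean()), float(v.std())


def calibrate_noise(
    frame: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_k: float = 4.0,
    smooth_sigma: float = 2.0,
) -> NoiseCalibration:
    """Estimate robust background mean and SD of one frame.

    Foreground (spots, nucleus) is excluded via the complement of an Otsu
    mask on a smoothed copy, unless the Otsu split does not actually separate
    bright structure (pure-noise frame), in which case the whole frame is
    background.  A user ROI ``mask`` (True = background) overrides both.
    Statistics are sigma-clipped within the chosen region.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise DetectionError("empty frame")
    if mask is not None:
        source = "user-ROI"
        bg = img[np.asarray(mask, dtype=bool)]
        if bg.size == 0:
            raise DetectionError("empty background mask")
    else:
        source = "otsu-complement"
        m0, s0 = _sigma_clipped_stats(img)
        bg = img
        if s0 > 0:
            sm = gaussian(img, smooth_sigma, preserve_range=True)
            try:
                th = threshold_otsu(sm)
            except ValueError:  # constant image
                th = None
            if th is not None:
                fg = sm > th
                # only trust the split if the "foreground" is genuinely bright
                if 0 < fg.mean() < 0.5 and (img[fg].mean() - m0) > 2.0 * s0:
                    bg = img[~fg]
    mean, sd = _sigma_clipped_stats(bg)
    if sd <= 0:
        raise DetectionError("background SD is zero (constant image)")
    return NoiseCalibration(mean, sd, threshold_k, source)


def _weighted_centroid(
    img: np.ndarray, x0: float, y0: float, psf_sigma: float, bg_mean: float, iters: int = 4
):
    """Iterated Gaussian-weighted centroid in a window of radius ceil(3*sigma)."""
    h, w = img.shape
    r = int(math.ceil(3.0 * psf_sigma))
    x, y = float(x0), float(y0)
    for _ in range(iters):
        cx, cy = int(round(x)), int(round(y))
        x0w, x1w = max(cx - r, 0), min(cx + r + 1, w)
        y0w, y1w = max(cy - r, 0), min(cy + r + 1, h)
        if x1w - x0w < 2 or y1w - y0w < 2:
            break
        win = img[y0w:y1w, x0w:x1w] - bg_mean
        xs = np.arange(x0w, x1w, dtype=float)
        ys = np.arange(y0w, y1w, dtype=float)
        wgt = np.exp(
            -((ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2) / (2 * psf_sigma**2)
        )
        num = wgt * np.clip(win, 0, None)
        tot = num.sum()
        if tot <= 0:
            break
        xn = float((num * xs[None, :]).sum() / tot)
        yn = float((num * ys[:, None]).sum() / tot)
        if abs(xn - x) < 1e-4 and abs(yn - y) < 1e-4:
            x, y = xn, yn
            break
        x, y = xn, yn
    # Gaussian-weighted least-squares amplitude at the refined position
    cx, cy = int(round(x)), int(round(y))
    x0w, x1w = max(cx - r, 0), min(cx + r + 1, w)
    y0w, y1w = max(cy - r, 0), min(cy + r + 1, h)
    win = img[y0w:y1w, x0w:x1w] - bg_mean
    xs = np.arange(x0w, x1w, dtype=float)
    ys = np.arange(y0w, y1w, dtype=float)
    wgt = np.exp(
        -((ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2) / (2 * psf_sigma**2)
    )
    denom = (wgt**2).sum()
    amplitude = float((wgt * win).sum() / denom) if denom > 0 else 0.0
    return x, y, amplitude


def _merge_close(dets: list[Detection], radius: float) -> list[Detection]:
    """Merge detections within one PSF of each other, keeping the brighter."""
    kept: list[Detection] = []
    for d in sorted(dets, key=lambda d: (-d.snr, d.x, d.y)):
        if all((d.x - k.x) ** 2 + (d.y - k.y) ** 2 >= radius**2 for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.x, d.y))
    return kept


def detect_particles(
    frame: np.ndarray,
    calib: NoiseCalibration,
    psf_sigma: float,
    frame_index: int = 0,
    channel: str = "",
    candidate_k: float = 2.0,
) -> list[Detection]:
    """Detect sub-pixel puncta in one frame.

    Band-pass: difference of Gaussians with sigma_low = psf_sigma and
    sigma_high = 3 * psf_sigma.  Candidates are band-pass local maxima above a
    low gate (``candidate_k`` robust SDs of the band-passed frame); each is
    refined and kept if its amplitude SNR reaches ``calib.threshold_k``.
    Duplicate maxima within one PSF are merged to the brighter.  An empty list
    is a valid result.
    """
    if psf_sigma <= 0:
        raise ParameterError("psf_sigma must be > 0")
    img = np.asarray(frame, dtype=float)
    dog = difference_of_gaussians(img, psf_sigma, 3.0 * psf_sigma)
    mad = float(np.median(np.abs(dog - np.median(dog))))
    dog_sd = 1.4826 * mad if mad > 0 else float(dog.std())
    if dog_sd == 0:
        return []
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(round(psf_sigma))),
        threshold_abs=candidate_k * dog_sd,
        exclude_border=False,
    )
    dets: list[Detection] = []
    for py, px in peaks:
        x, y, amp = _weighted_centroid(
            img, float(px), float(py), psf_sigma, calib.background_mean
        )
        snr = amp / calib.background_sd
        if snr < calib.threshold_k:
            continue
        if not (0 <= x < img.shape[1] and 0 <= y < img.shape[0]):
            continue
        dets.append(
            Detection(
                frame=frame_index,
                x=x,
                y=y,
                intensity=amp * 2.0 * math.pi * psf_sigma**2,
                snr=snr,
                channel=channel,
            )
        )
    return _merge_close(dets, 2.0 * psf_sigma)


def nucleus_mask(nucleus_frame: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Boolean nucleus mask from the counterstain channel (largest Otsu blob)."""
    sm = gaussian(np.asarray(nucleus_frame, dtype=float), smooth_sigma,
                  preserve_range=True)
    th = threshold_otsu(sm)
    mask = sm > th
    lbl, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum(mask, lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    return mask


def detect_brightest(
    frame: np.ndarray,
    calib: NoiseCalibration,
    psf_sigma: float,
    mask: np.ndarray | None = None,
    frame_index: int = 0,
    channel: str = "",
) -> Detection:
    """Locate the single brightest spot (optionally within a nucleus mask).

    Bypasses thresholding: intended for locus-type probes where exactly one
    tagged site exists per nucleus.
    """
    img = np.asarray(frame, dtype=float)
    dog = difference_of_gaussians(img, psf_sigma, 3.0 * psf_sigma)
    search = dog.copy()
    if mask is not None:
        search[~np.asarray(mask, dtype=bool)] = -np.inf
    py, px = np.unravel_index(int(np.argmax(search)), search.shape)
    x, y, amp = _weighted_centroid(
        img, float(px), float(py), psf_sigma, calib.background_mean
    )
    return Detection(
        frame=frame_index,
        x=x,
        y=y,
        intensity=amp * 2.0 * math.pi * psf_sigma**2,
        snr=amp / calib.background_sd,
        channel=channel,
    )
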