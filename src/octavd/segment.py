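"""Vessel segmentation: denoise -> multiscale vesselness -> local threshold.

The vesselness measure is the classic 2-D Hessian-eigenvalue filter for
bright curvilinear structures. At each scale s the image is convolved with
scale-normalized Gaussian second derivatives (multiplied by s^2 so
responses are comparable across scales); with eigenvalues ordered
|l1| <= |l2|, a pixel on a bright vessel has l2 strongly negative and
|l1| small. The response is

    V_s = exp(-R_B^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2)))

with blobness ratio R_B = l1/l2 and structureness S = sqrt(l1^2 + l2^2),
set to zero wherever l2 > 0 (dark-ridge / bright-background geometry).
The final map is the pointwise maximum over scales, in [0, 1].

Binarization thresholds each pixel against a local background statistic
(median by default) plus an offset, then removes connected components
below a size floor. All filters use reflect (symmetric) boundary handling
so border vessels are not lost.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

from .config import SegmentConfig
from .types import EnFaceImage, as_pixels

__all__ = [
    "denoise",
    "frangi_vesselness",
    "adaptive_threshold",
    "segment_vessels",
]

#: Gaussian kernel truncation radius, in standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def denoise(image, median_radius: int = 1, gaussian_sigma: float = 1.0):
    """Median filter (square window, side 2r+1) followed by Gaussian smoothing.

    Either step is disabled by passing 0. Output range stays within the
    input range (the median is order-preserving; the Gaussian is a convex
    combination under reflect padding).
    """
    if median_radius < 0 or gaussian_sigma < 0:
        raise ValueError("median_radius and gaussian_sigma must be >= 0")
    px = as_pixels(image)
    out = px
    if median_radius > 0:
        out = ndimage.median_filter(out, size=2 * median_radius + 1, mode="reflect")
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(
            out, gaussian_sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE
        )
    if out is px:
        out = px.copy()
    if isinstance(image, EnFaceImage):
        return image.with_pixels(out)
    return out


def _hessian(px: np.ndarray, sigma: float):
    """Scale-normalized Hessian components (Hyy, Hxy, Hxx) at scale sigma."""
    s2 = sigma * sigma
    opts = dict(mode="reflect", truncate=GAUSSIAN_TRUNCATE)
    hyy = s2 * ndimage.gaussian_filter(px, sigma, order=(2, 0), **opts)
    hxy = s2 * ndimage.gaussian_filter(px, sigma, order=(1, 1), **opts)
    hxx = s2 * ndimage.gaussian_filter(px, sigma, order=(0, 2), **opts)
    return hyy, hxy, hxx


def frangi_vesselness(
    image,
    scales: Sequence[float] = (1.0, 1.5, 2.0, 2.5),
    beta: float = 0.5,
    c: Union[str, float] = "auto",
):
    """Multiscale bright-vessel vesselness map in [0, 1].

    ``c="auto"`` uses half the maximal Hessian Frobenius norm at each
    scale; a numeric ``c`` is shared across scales. Constant images (zero
    Hessian everywhere) map to all-zero vesselness.
    """
    vmap, _ = _frangi(image, scales, beta, c)
    if isinstance(image, EnFaceImage):
        return image.with_pixels(vmap)
    return vmap


def _frangi(image, scales, beta, c):
    """Vesselness plus the maximal Hessian Frobenius norm over all scales."""
    scales = tuple(scales)
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    px = as_pixels(image)
    # zero-mean input makes additive-offset invariance exact despite the
    # truncated derivative kernels' tiny nonzero sums
    px = px - px.mean()

    best = np.zeros_like(px)
    s_peak = 0.0
    for s in scales:
        hyy, hxy, hxx = _hessian(px, s)
        # closed-form eigenvalues of the symmetric 2x2 Hessian
        mean = 0.5 * (hxx + hyy)
        root = np.sqrt((0.5 * (hxx - hyy)) ** 2 + hxy**2)
        e1, e2 = mean + root, mean - root
        swap = np.abs(e1) > np.abs(e2)
        lam1 = np.where(swap, e2, e1)  # |lam1| <= |lam2|
        lam2 = np.where(swap, e1, e2)

        structureness = np.sqrt(lam1**2 + lam2**2)
        s_peak = max(s_peak, float(structureness.max()))
        if isinstance(c, str):
            if c != "auto":
                raise ValueError('c must be a positive number or "auto"')
            c_s = 0.5 * float(structureness.max())
        else:
            c_s = float(c)
        if c_s <= 1e-12:  # numerically flat at this scale: no structure
            continue

        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
        v = np.exp(-rb2 / (2.0 * beta**2)) * (
            1.0 - np.exp(-(structureness**2) / (2.0 * c_s**2))
        )
        v = np.where(lam2 > 0, 0.0, v)  # bright-vessel convention
        np.maximum(best, v, out=best)

    return np.clip(best, 0.0, 1.0), s_peak


def adaptive_threshold(
    vmap,
    window: int = 61,
    offset: float = 0.03,
    min_object_px: int = 15,
    method: str = "median",
) -> np.ndarray:
    """Binarize: pixel is vessel iff value > (local statistic over window) + offset.

    The local statistic is the median (default; robust to the vessel
    pixels themselves inflating the estimate) or the mean. A positive
    ``offset`` raises the threshold, keeping flat background (value =
    local statistic) out of the vessel class. Components smaller than
    ``min_object_px`` pixels (8-connectivity) are removed afterwards;
    despeckling can only lower the vessel density.
    """
    px = as_pixels(vmap)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window >= min(px.shape):
        raise ValueError(
            f"window {window} must be smaller than the image {px.shape}"
        )
    if method == "median":
        local = ndimage.median_filter(px, size=window, mode="reflect")
    elif method == "mean":
        local = ndimage.uniform_filter(px, size=window, mode="reflect")
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    binary = px > local + offset
    if min_object_px > 1:
        binary = remove_small_objects(
            binary, max_size=min_object_px - 1, connectivity=2
        )
    return binary


def segment_vessels(image, cfg: Optional[SegmentConfig] = None) -> np.ndarray:
    """Full segmentation chain on one (already stripe-filtered) en face image.

    A frame-level flow-signal check runs first: if no pixel's multiscale
    Hessian norm exceeds ``cfg.min_signal`` after denoising, the frame has
    no vascular contrast (only residual noise texture, whose ridges a
    contrast-normalized vesselness filter would otherwise amplify) and an
    empty mask is returned. Frames with genuine flow signal are untouched
    by the check.
    """
    cfg = cfg or SegmentConfig()
    cfg.validate()
    px = as_pixels(image)
    px = denoise(px, cfg.median_radius, cfg.gaussian_sigma)
    vmap, s_peak = _frangi(px, cfg.frangi_scales, cfg.frangi_beta, cfg.frangi_c)
    if s_peak < cfg.min_signal:
        return np.zeros_like(vmap, dtype=bool)
    return adaptive_threshold(
        vmap,
        cfg.threshold_window,
        cfg.threshold_offset,
        cfg.min_object_px,
        cfg.threshold_method,
    )
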