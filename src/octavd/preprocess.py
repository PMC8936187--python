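"""Motion-stripe and illumination-gradient removal via directional FFT bandpass.

En face AS-OCTA frames carry full-width line artifacts along the fast-scan
axis (horizontal rows) from eye motion during acquisition, plus slow
illumination gradients. Both live in compact regions of the 2-D spectrum:
stripes on the frequency axis perpendicular to their orientation, gradients
near DC. The filter attenuates structures outside the
[filter_small_px, filter_large_px] size band with Gaussian-tapered radial
edges and zeroes an angular wedge along the stripe-carrying axis.

The filter is linear up to the optional final rescaling; the DC component
(mean intensity) is always preserved, and every mask value lies in [0, 1]
so non-DC spectral energy is never amplified.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from scipy.special import ndtr

from .config import BandpassConfig
from .types import EnFaceImage, as_pixels

__all__ = ["fft_bandpass", "bandpass_mask", "nondc_energy"]


def bandpass_mask(shape: Tuple[int, int], cfg: BandpassConfig) -> np.ndarray:
    """Frequency-domain transfer function (unshifted fft2 layout), in [0, 1].

    Radial passband: smooth steps (Gaussian CDF edges, relative width
    ``gaussian_edge``) at 1/filter_large_px and 1/filter_small_px cycles/px.
    Directional wedge: frequencies within (100 - direction_tolerance_pct)%
    of the maximal 45 deg half-angle of the stripe axis are zeroed — a
    full-width stripe lives exactly on that axis, so even a narrow wedge
    removes it completely while sparing stripe-oriented vessels. DC is
    forced to 1.
    """
    cfg.validate(shape)
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)

    f_lo = 1.0 / cfg.filter_large_px
    f_hi = 1.0 / cfg.filter_small_px
    edge = max(cfg.gaussian_edge, 1e-6)
    # smooth step up at f_lo (suppress large structures), down at f_hi
    mask = ndtr((r - f_lo) / (edge * f_lo)) * ndtr((f_hi - r) / (edge * f_hi))

    if cfg.suppress_direction != "none" and cfg.direction_tolerance_pct < 100:
        half_angle = np.deg2rad(45.0 * (100.0 - cfg.direction_tolerance_pct) / 100.0)
        if cfg.suppress_direction == "horizontal":
            # horizontal stripes vary along y only -> energy on the fy axis
            off_axis = np.arctan2(np.abs(fx), np.abs(fy))
        else:
            off_axis = np.arctan2(np.abs(fy), np.abs(fx))
        wedge = off_axis <= half_angle
        wedge[0, 0] = False
        mask = np.where(wedge, 0.0, mask)

    mask[0, 0] = 1.0  # DC preserved by convention
    return mask


def fft_bandpass(
    image: Union[EnFaceImage, np.ndarray],
    cfg: Optional[BandpassConfig] = None,
    rescale: Optional[str] = None,
):
    """Apply the directional bandpass; returns the same type as the input.

    ``rescale`` overrides ``cfg.rescale``: "stretch" min-max rescales the
    filtered image back to the input's value range (the usual autoscale
    convention), "clip" clips to the input range, "none" returns the raw
    linear output. A constant image passes through unchanged.
    """
    cfg = cfg or BandpassConfig()
    mode = rescale if rescale is not None else cfg.rescale
    if mode not in ("stretch", "clip", "none"):
        raise ValueError(f"unknown rescale mode {mode!r}")
    px = as_pixels(image)
    cfg.validate(px.shape)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")

    in_min, in_max = float(px.min()), float(px.max())
    if in_max == in_min:  # degenerate: no non-DC energy to filter
        out = px.copy()
    else:
        mask = bandpass_mask(px.shape, cfg)
        out = np.fft.ifft2(np.fft.fft2(px) * mask).real
        if mode == "stretch":
            lo, hi = float(out.min()), float(out.max())
            if hi > lo:
                out = in_min + (out - lo) * (in_max - in_min) / (hi - lo)
            else:
                out = np.full_like(out, in_min)
        elif mode == "clip":
            out = np.clip(out, in_min, in_max)

    if isinstance(image, EnFaceImage):
        return image.with_pixels(out)
    return out


def nondc_energy(image: Union[EnFaceImage, np.ndarray]) -> float:
    """Total spectral energy excluding the DC bin (Parseval, unnormalized)."""
    px = as_pixels(image)
    spec = np.abs(np.fft.fft2(px)) ** 2
    return float(spec.sum() - spec[0, 0])
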