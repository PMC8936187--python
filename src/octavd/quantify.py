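"""Vessel-density quantification.

Vessel density (VD) is the percentage of vessel-classified pixels in the
scan area: VD = 100 * P / A, with P the vessel-pixel count and A the
total pixel count of the analyzed frame. Each corneolimbal sector is its
own scan, so A is the (optionally margin-cropped) full frame.

``dye_restricted_vd`` supports validation against an intra-operatively
dye-labelled reference: only vessel pixels inside the traced dye mask are
counted, while A stays the full frame so restricted and unrestricted VD
share a scale (restricted VD <= unrestricted VD by construction).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .config import PipelineConfig, QuantifyConfig
from .preprocess import fft_bandpass
from .segment import segment_vessels
from .types import EnFaceImage, SectorRecord

__all__ = ["vessel_density", "dye_restricted_vd", "quantify_image"]


def _as_bool(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr.astype(bool)


def vessel_density(mask, roi=None) -> float:
    """VD = 100 * P / A, percent; ``roi=None`` means the whole frame."""
    m = _as_bool(mask, "mask")
    if roi is None:
        area = m.size
        vessels = int(np.count_nonzero(m))
    else:
        r = _as_bool(roi, "roi")
        if r.shape != m.shape:
            raise ValueError(f"mask shape {m.shape} != roi shape {r.shape}")
        area = int(np.count_nonzero(r))
        vessels = int(np.count_nonzero(m & r))
    if area == 0:
        raise ValueError("roi is empty: vessel density is undefined (A = 0)")
    return 100.0 * vessels / area


def dye_restricted_vd(mask, dye_mask, denominator: str = "frame") -> float:
    """VD counting only vessel pixels inside the dye-labelled reference mask.

    ``denominator="frame"`` (default) keeps A = full frame;
    ``denominator="dye_mask"`` uses the dye-mask area instead.
    """
    m = _as_bool(mask, "mask")
    d = _as_bool(dye_mask, "dye_mask")
    if d.shape != m.shape:
        raise ValueError(f"mask shape {m.shape} != dye_mask shape {d.shape}")
    if not d.any():
        raise ValueError("dye_mask is empty")
    if denominator == "frame":
        return 100.0 * int(np.count_nonzero(m & d)) / m.size
    if denominator == "dye_mask":
        return vessel_density(m, d)
    raise ValueError(f"unknown denominator {denominator!r}")


def quantify_image(
    image: EnFaceImage, cfg: Optional[PipelineConfig] = None
) -> SectorRecord:
    """Run preprocess -> segment -> VD on one en face image; emit one record.

    The image must carry eye/sector/layer/visit metadata (the cohort
    manifest is the authoritative source for these).
    """
    cfg = cfg or PipelineConfig()
    missing = [
        k
        for k in ("eye_id", "sector", "layer", "visit", "implant")
        if getattr(image, k) is None
    ]
    if missing:
        raise ValueError(f"image metadata missing fields: {', '.join(missing)}")

    filtered = fft_bandpass(image.pixels, cfg.preprocess)
    crop = cfg.quantify.margin_crop
    if crop > 0:
        if 2 * crop >= min(filtered.shape):
            raise ValueError(f"margin_crop {crop} leaves no analyzable frame")
        filtered = filtered[crop:-crop, crop:-crop]
    mask = segment_vessels(filtered, cfg.segment)
    return SectorRecord(
        eye_id=str(image.eye_id),
        sector=str(image.sector),
        layer=str(image.layer),
        visit=str(image.visit),
        implant=bool(image.implant),
        vd=vessel_density(mask),
    )
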