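"""Pipeline configuration: dataclasses with YAML round-trip.

Every run writes its fully-resolved configuration next to its outputs so a
result can be reproduced from the output directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import yaml


@dataclass
class BandpassConfig:
    """Directional FFT bandpass used for motion-stripe removal.

    ``filter_small_px`` / ``filter_large_px`` bound the passband in
    structure size (pixels): structures smaller than the former or larger
    than the latter are attenuated with Gaussian-tapered radial edges.
    ``suppress_direction`` zeroes an angular wedge of the spectrum along
    the axis that carries stripes of that orientation.
    ``direction_tolerance_pct`` is the percentage of frequency directions
    *tolerated* (left untouched): the remaining (100 - pct)% of the
    maximal 45 deg wedge around the stripe axis is zeroed, so the default
    90% removes a narrow 4.5 deg wedge that covers full-width stripe
    artifacts while sparing stripe-oriented vessels.
    """

    filter_small_px: float = 3.0
    filter_large_px: float = 40.0
    suppress_direction: str = "horizontal"  # horizontal | vertical | none
    direction_tolerance_pct: float = 90.0
    gaussian_edge: float = 0.05
    rescale: str = "clip"  # clip | stretch | none

    def validate(self, image_shape: Optional[Tuple[int, int]] = None) -> None:
        if not 0 < self.filter_small_px < self.filter_large_px:
            raise ValueError(
                "require 0 < filter_small_px < filter_large_px, got "
                f"{self.filter_small_px}, {self.filter_large_px}"
            )
        if image_shape is not None and self.filter_large_px >= min(image_shape):
            raise ValueError("filter_large_px must be smaller than the image")
        if self.suppress_direction not in ("horizontal", "vertical", "none"):
            raise ValueError(f"unknown suppress_direction {self.suppress_direction!r}")
        if not 0.0 <= self.direction_tolerance_pct <= 100.0:
            raise ValueError("direction_tolerance_pct must lie in [0, 100]")
        if self.rescale not in ("stretch", "clip", "none"):
            raise ValueError(f"unknown rescale mode {self.rescale!r}")


@dataclass
class SegmentConfig:
    """Denoise -> multiscale vesselness -> local adaptive threshold.

    Frangi scales are Gaussian sigmas in pixels, roughly the vessel radii
    of interest (1-2.5 px covers 30-75 um calibers at 15 um/px; larger
    scales halo the response and inflate VD). ``frangi_c="auto"`` sets the
    structureness scale to half the maximal Hessian Frobenius norm at each
    scale, the conventional data-driven choice. The local threshold
    statistic defaults to the median, which stays anchored to the
    background level even where vessels fill a quarter of the window; the
    plain local mean is available as ``threshold_method="mean"``.
    ``min_signal`` is a frame-level quality floor: a frame whose maximal
    Hessian norm never reaches it carries no vascular flow contrast and
    segments to an empty mask (0 disables the check).
    """

    median_radius: int = 1
    gaussian_sigma: float = 0.5
    frangi_scales: Tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    frangi_beta: float = 0.5
    frangi_c: Union[str, float] = "auto"
    threshold_method: str = "median"  # median | mean
    threshold_window: int = 61
    threshold_offset: float = 0.025
    min_object_px: int = 15
    min_signal: float = 0.07  # frame-level flow-signal floor (Hessian norm)

    def validate(self) -> None:
        scales = tuple(self.frangi_scales)
        if len(scales) == 0:
            raise ValueError("frangi_scales must be non-empty")
        if any(s <= 0 for s in scales) or list(scales) != sorted(scales):
            raise ValueError("frangi_scales must be positive and increasing")
        if self.threshold_window < 3 or self.threshold_window % 2 == 0:
            raise ValueError("threshold_window must be odd and >= 3")
        if self.frangi_beta <= 0:
            raise ValueError("frangi_beta must be > 0")
        if self.median_radius < 0 or self.gaussian_sigma < 0:
            raise ValueError("median_radius and gaussian_sigma must be >= 0")
        if isinstance(self.frangi_c, str) and self.frangi_c != "auto":
            raise ValueError('frangi_c must be a positive number or "auto"')
        if self.threshold_method not in ("median", "mean"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.min_signal < 0:
            raise ValueError("min_signal must be >= 0")


@dataclass
class QuantifyConfig:
    """VD computation options.

    ``margin_crop`` removes a border of that many pixels from the frame
    before counting (A = pixels after the crop); the default keeps the
    whole frame. ``restricted_denominator`` selects the area term for
    dye-restricted VD: the full frame (keeps restricted and unrestricted
    VD on one scale) or the dye-mask area.
    """

    margin_crop: int = 0
    restricted_denominator: str = "frame"  # frame | dye_mask

    def validate(self) -> None:
        if self.margin_crop < 0:
            raise ValueError("margin_crop must be >= 0")
        if self.restricted_denominator not in ("frame", "dye_mask"):
            raise ValueError(f"unknown denominator {self.restricted_denominator!r}")


@dataclass
class StatsConfig:
    baseline_visit: str = "pre"
    visits: Optional[Tuple[str, ...]] = None  # None = all visits in the table
    zero_method: str = "wilcox"  # drop zero differences (classic) | pratt
    exact_cutoff: int = 15  # exact Wilcoxon enumeration up to this n (no ties)
    alpha: float = 0.05

    def validate(self) -> None:
        if self.zero_method not in ("wilcox", "pratt"):
            raise ValueError(f"unknown zero_method {self.zero_method!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    preprocess: BandpassConfig = field(default_factory=BandpassConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.preprocess.validate()
        self.segment.validate()
        self.quantify.validate()
        self.stats.validate()

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML; restored on load
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            preprocess=BandpassConfig(**d.get("preprocess", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            quantify=QuantifyConfig(**d.get("quantify", {})),
            stats=StatsConfig(**d.get("stats", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )
        cfg.segment.frangi_scales = tuple(cfg.segment.frangi_scales)
        if cfg.stats.visits is not None:
            cfg.stats.visits = tuple(cfg.stats.visits)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj
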