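"""Core domain containers shared across the pipeline.

An *en face* angiogram is a 2-D grayscale projection of an AS-OCTA volume
restricted to one depth layer (episcleral, or full conjunctival-to-scleral
thickness), acquired for one corneolimbal sector of one eye at one visit.
All image intensities are carried internally as float64 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

#: Canonical sector order; also the tie-break order for index-sector selection.
SECTOR_ORDER: Tuple[str, ...] = (
    "superior",
    "superior_nasal",
    "nasal",
    "inferior_nasal",
    "inferior",
    "inferior_temporal",
    "temporal",
)

#: Default visit schedule (baseline plus follow-ups).
VISIT_ORDER: Tuple[str, ...] = ("pre", "week1", "month1", "month3", "month6")

LAYERS: Tuple[str, ...] = ("episcleral", "full")


@dataclass
class EnFaceImage:
    """One grayscale en face angiogram plus its acquisition metadata."""

    pixels: np.ndarray
    eye_id: Optional[str] = None
    sector: Optional[str] = None
    layer: Optional[str] = None
    visit: Optional[str] = None
    implant: Optional[bool] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"en face image must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("en face image contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this record with new pixel data, metadata preserved."""
        return EnFaceImage(
            pixels=pixels,
            eye_id=self.eye_id,
            sector=self.sector,
            layer=self.layer,
            visit=self.visit,
            implant=self.implant,
        )


def as_pixels(image) -> np.ndarray:
    """Accept an EnFaceImage or a bare 2-D array; return float64 pixels."""
    if isinstance(image, EnFaceImage):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SectorRecord:
    """One vessel-density measurement: eye x sector x layer x visit."""

    eye_id: str
    sector: str
    layer: str
    visit: str
    implant: bool
    vd: float  # percent in [0, 100]

    def __post_init__(self) -> None:
        if not 0.0 <= self.vd <= 100.0:
            raise ValueError(f"vd must lie in [0, 100], got {self.vd}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test on cohort VD values.

    ``n`` counts the informative pairs (Wilcoxon) or complete blocks
    (Friedman) that entered the test. For paired tests, ``mean_difference``
    is the mean follow-up minus baseline difference over all pairs and
    ``ci95`` its paired-t 95% confidence interval.
    """

    test_name: str
    statistic: float
    p_value: float
    n: int
    mean_difference: Optional[float] = None
    ci95: Optional[Tuple[float, float]] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 low must not exceed high")

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
        }
        if self.mean_difference is not None:
            d["mean_difference"] = float(self.mean_difference)
        if self.ci95 is not None:
            d["ci95"] = [float(self.ci95[0]), float(self.ci95[1])]
        if self.n_excluded:
            d["n_excluded"] = int(self.n_excluded)
        return d
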