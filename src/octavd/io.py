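"""File formats and the end-to-end pipeline runner.

Images are 8- or 16-bit single-channel TIFF or PNG, normalized to [0, 1]
by bit depth on read. Binary masks travel as 0/255 TIFF. Cohort tables are
long-format CSV (eye_id, sector, layer, visit, implant, vd); the manifest
maps image files to their metadata and is authoritative — the filename
pattern ``{eye}_{sector}_{layer}_{visit}`` is only a fallback. Every run
writes its resolved configuration and the package version beside its
outputs.
"""

from __future__ import annotations

import json
import logging
import re
import time
from pathlib import Path
from typing import Iterable, List, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cohort_stats import serial_analysis
from .config import PipelineConfig
from .quantify import quantify_image
from .types import EnFaceImage, SECTOR_ORDER, SectorRecord

log = logging.getLogger("octavd")

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_manifest",
    "records_to_frame",
    "run_pipeline",
]

_FILENAME_PATTERN = re.compile(
    r"(?P<eye>[^_]+)_(?P<sector>[a-z_]+?)_(?P<layer>episcleral|full)_(?P<visit>[^_.]+)"
)


def _normalize(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ValueError(f"{path}: unsupported image dtype {arr.dtype}")


def read_image(path, **metadata) -> EnFaceImage:
    """Read a grayscale TIFF/PNG as an EnFaceImage normalized to [0, 1].

    Metadata fields not given as keyword arguments are parsed from the
    filename pattern ``{eye}_{sector}_{layer}_{visit}`` when it matches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise ValueError(f"could not read image {path}: {exc}") from exc
    px = _normalize(np.asarray(arr), path)

    meta = dict(metadata)
    m = _FILENAME_PATTERN.match(path.stem)
    if m:
        meta.setdefault("eye_id", m.group("eye"))
        meta.setdefault("sector", m.group("sector"))
        meta.setdefault("layer", m.group("layer"))
        meta.setdefault("visit", m.group("visit"))
    return EnFaceImage(px, **meta)


def write_image(path, pixels: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8-bit (default) or 16-bit TIFF/PNG."""
    path = Path(path)
    px = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(px * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(px * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 8-bit TIFF."""
    tifffile.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask back to boolean."""
    arr = tifffile.imread(Path(path))
    return np.asarray(arr) > 127


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV: file, eye_id, sector, layer, visit, implant."""
    df = pd.read_csv(path)
    required = {"file", "eye_id", "sector", "layer", "visit", "implant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["sector"]) - set(SECTOR_ORDER)
    if bad:
        raise ValueError(f"manifest contains unknown sectors: {sorted(bad)}")
    df["implant"] = df["implant"].astype(bool)
    return df


def records_to_frame(records: Iterable[SectorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "eye_id": r.eye_id,
                "sector": r.sector,
                "layer": r.layer,
                "visit": r.visit,
                "implant": r.implant,
                "vd": r.vd,
            }
            for r in records
        ],
        columns=["eye_id", "sector", "layer", "visit", "implant", "vd"],
    )


def run_pipeline(
    manifest: Union[pd.DataFrame, str, Path],
    config: Optional[PipelineConfig] = None,
    outdir: Union[str, Path] = "octavd_out",
    manifest_root: Optional[Path] = None,
) -> dict:
    """Execute preprocess -> segment -> quantify -> analyze over a manifest.

    Writes the VD table (vd_table.csv), per-layer summaries and JSON stats
    reports, and the resolved config, into ``outdir``. Returns a dict with
    the VD table and per-layer SerialReports. Deterministic for fixed
    inputs and config.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if not isinstance(manifest, pd.DataFrame):
        manifest_root = manifest_root or Path(manifest).parent
        manifest = read_manifest(manifest)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records: List[SectorRecord] = []
    for row in manifest.itertuples(index=False):
        fpath = Path(row.file)
        if manifest_root is not None and not fpath.is_absolute():
            fpath = manifest_root / fpath
        t0 = time.perf_counter()
        try:
            img = read_image(
                fpath,
                eye_id=str(row.eye_id),
                sector=str(row.sector),
                layer=str(row.layer),
                visit=str(row.visit),
                implant=bool(row.implant),
            )
            rec = quantify_image(img, cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on image {fpath}: {exc}") from exc
        log.info(
            "quantified %s (%s/%s/%s/%s): vd=%.2f [%.2fs]",
            fpath.name, rec.eye_id, rec.sector, rec.layer, rec.visit,
            rec.vd, time.perf_counter() - t0,
        )
        records.append(rec)

    vd_table = records_to_frame(records)
    vd_table.to_csv(outdir / "vd_table.csv", index=False)

    reports = {}
    for layer in vd_table["layer"].unique():
        layer_df = vd_table[vd_table["layer"] == layer]
        if layer_df["visit"].nunique() < 2 or layer_df["eye_id"].nunique() < 1:
            continue
        if cfg.stats.baseline_visit not in set(layer_df["visit"]):
            continue
        rep = serial_analysis(vd_table, layer=layer, cfg=cfg.stats)
        rep.summary.to_csv(outdir / f"summary_{layer}.csv", index=False)
        (outdir / f"stats_{layer}.json").write_text(
            json.dumps(rep.report, indent=2, allow_nan=True)
        )
        reports[layer] = rep

    cfg.save(outdir / "config.yaml")
    (outdir / "VERSION").write_text(f"octavd {__version__}\n")
    return {"vd_table": vd_table, "reports": reports}
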