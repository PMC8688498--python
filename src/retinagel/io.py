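"""Shared I/O, run configuration, logging, and error types.

All raster input and output goes through TIFF (single- or multi-page,
8- or 16-bit); intensities are normalized to floats in [0, 1] on read.
Physical metadata (pixel size, z-step) comes from a JSON sidecar named
``<image>.meta.json`` next to the image, or from explicit arguments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger("retinagel")

SCHEMA_VERSION = "1.0"

#: Default global seed used by every generator when none is supplied.
DEFAULT_SEED = 20211220


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class RetinagelError(Exception):
    """Base class for all package errors."""


class PresetError(RetinagelError):
    """A synthetic-data preset is invalid or unknown."""


class PackingError(RetinagelError):
    """Requested object count cannot be placed within the field."""


class DegenerateImageError(RetinagelError):
    """Image is constant (or empty) where a threshold is required."""


class FitError(RetinagelError):
    """A least-squares fit failed to converge."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


class NoGelPointError(RetinagelError):
    """Storage and loss moduli never cross."""


class NoPlateauError(RetinagelError):
    """Storage modulus never settles within the plateau band."""


class MetadataError(RetinagelError):
    """Required physical metadata (pixel size, z-step) is missing."""


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Pipeline constants shared across the image-analysis modules.

    The defaults are the working values of the quantification pipelines:
    dual thresholds at 10% and 30% of normalized intensity, removal of
    connected components under 10 px, a 5 px border deletion for the
    engraftment segmentation, 200 µm interface segments and a 2 px
    gel-boundary gap tolerance.
    """

    pixel_size: float = Field(1.0, gt=0, description="µm per pixel")
    z_step: float = Field(1.0, gt=0, description="µm per z slice")
    low_threshold: float = Field(0.10, gt=0, lt=1)
    high_threshold: float = Field(0.30, gt=0, lt=1)
    blur_sigma_px: float = Field(1.0, ge=0)
    opening_radius_px: int = Field(2, ge=1)
    closing_radius_px: int = Field(2, ge=1)
    # the viability pipeline opens with a 1 px disc so that its
    # small-object rule (< min_object_px removed) stays meaningful
    viability_opening_radius_px: int = Field(1, ge=1)
    min_object_px: int = Field(10, ge=1)
    border_px: int = Field(5, ge=0)
    segment_length_um: float = Field(200.0, gt=0)
    gap_tolerance_px: float = Field(2.0, ge=0)
    min_peak_separation_um: float = Field(5.0, gt=0)
    seed: int = DEFAULT_SEED
    out_dir: str = "results"

    @model_validator(mode="after")
    def _check_thresholds(self) -> "RunConfig":
        if self.low_threshold >= self.high_threshold:
            raise ValueError("low_threshold must be < high_threshold")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CONFIG = RunConfig()


# --------------------------------------------------------------------------
# Image I/O
# --------------------------------------------------------------------------

def _dtype_scale(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def read_image(path: str | Path, require_pixel_size: bool = False,
               pixel_size: float | None = None,
               z_step: float | None = None) -> tuple[np.ndarray, dict]:
    """Read a TIFF image or stack as float intensities in [0, 1].

    Returns ``(data, meta)`` where ``data`` is 2D (single page) or 3D
    (``(z, y, x)`` for a multi-page file) and ``meta`` carries
    ``pixel_size`` / ``z_step`` in µm when known.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = tifffile.imread(path)
    data = np.asarray(raw, dtype=np.float64) / _dtype_scale(np.asarray(raw))
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    alt = path.parent / (path.stem + ".meta.json")
    for candidate in (sidecar, alt):
        if candidate.exists():
            meta.update(json.loads(candidate.read_text()))
            break
    if pixel_size is not None:
        meta["pixel_size"] = pixel_size
    if z_step is not None:
        meta["z_step"] = z_step
    if require_pixel_size and "pixel_size" not in meta:
        raise MetadataError(
            f"pixel size required but not found for {path}; provide a "
            f"*.meta.json sidecar or an explicit --pixel-size")
    return data, meta


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write a float [0, 1] or integer label array as 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr, 0.0, 1.0)
        arr = np.round(arr * 65535).astype(np.uint16)
    else:
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.to_dict(orient="list")}
    if isinstance(obj, BaseModel):
        return _jsonable(obj.model_dump())
    return obj


def write_report(results: dict, path: str | Path,
                 config: RunConfig | None = None,
                 tables: dict[str, pd.DataFrame] | None = None) -> None:
    """Write a JSON report (plus optional CSV tables next to it).

    The report echoes the schema version, the configuration and its hash
    so a run can be reproduced from the report alone.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": config.model_dump() if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
        "results": _jsonable(results),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    for name, table in (tables or {}).items():
        table.to_csv(path.parent / f"{path.stem}.{name}.csv", index=False)
    logger.info("wrote report %s", path)


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    return doc
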