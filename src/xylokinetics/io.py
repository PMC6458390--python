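"""Reading and writing the package's file formats.

The measurement CSV is the raw-data exchange format, one row per
(sampling day, replicate), with the field-customary units in the
header::

    dag,replicate,area_um2,cell_count,extension_cm

On input it is converted to the canonical internal units (mm^2, mm);
on output converted back. Section images travel as 8-bit grayscale
TIFF or PNG, label maps as 16-bit TIFF with a ground-truth sidecar
JSON ``{"true_count": n}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import units
from .series import CANONICAL_COLUMNS

EXTERNAL_COLUMNS = ("dag", "replicate", "area_um2", "cell_count", "extension_cm")

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_ground_truth",
]


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV into a canonical-unit table.

    Raises ValueError naming the offending column (missing header) or
    row (non-numeric cell) on malformed input.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in EXTERNAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("dag", "area_um2", "cell_count", "extension_cm"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at row(s) "
                f"{list(bad[:5])}")
        if coerced.isna().any():
            raise ValueError(
                f"{path}: empty value in column '{col}' at row(s) "
                f"{list(raw.index[coerced.isna()][:5])}")
        raw[col] = coerced
    return pd.DataFrame({
        "dag": raw["dag"],
        "replicate": raw["replicate"],
        "area_mm2": units.um2_to_mm2(raw["area_um2"]),
        "cell_count": raw["cell_count"],
        "extension_mm": units.cm_to_mm(raw["extension_cm"]),
    })


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a canonical-unit table to the external CSV format."""
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    out = pd.DataFrame({
        "dag": table["dag"],
        "replicate": table["replicate"],
        "area_um2": units.mm2_to_um2(table["area_mm2"]),
        "cell_count": table["cell_count"],
        "extension_cm": units.mm_to_cm(table["extension_mm"]),
    })
    out.to_csv(path, index=False)


def write_image(image: np.ndarray, path) -> None:
    """Write an 8-bit grayscale image as TIFF or PNG by extension."""
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image, mode="L").save(path)


def read_image(path) -> np.ndarray:
    """Read a grayscale or RGB section image as a numpy array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def write_ground_truth(label_map: np.ndarray, true_count: int, path) -> None:
    """Write a 16-bit label map (TIFF) plus its sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(label_map, dtype=np.uint16))
    path.with_suffix(".json").write_text(
        json.dumps({"true_count": int(true_count)}))


def read_ground_truth(path):
    """Read a label-map TIFF and its sidecar JSON; returns (labels, count)."""
    path = Path(path)
    labels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return labels, int(meta["true_count"])
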