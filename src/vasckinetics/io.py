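"""Readers and writers for label masks and cell tables.

Conventions (enforced, never inferred):

* label masks are 3D integer TIFF stacks in (z, y, x) axis order;
* ``spacing`` is the per-axis voxel spacing in µm, in the same (z, y, x)
  order as the array; a voxel at index (k, j, i) has its center at physical
  coordinates (k·dz, j·dy, i·dx) µm;
* cell tables are CSV/TSV with µm coordinates in (x, y, z) columns and
  boolean marker flags encoded as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, SpacingError

#: columns every cell table must carry
REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um", "z_um")
#: recognized boolean marker flags (0/1 in files)
FLAG_COLUMNS = ("edu", "brdu", "ki67", "erg", "prox1", "lineage")
#: compartment labels a cell may carry
COMPARTMENTS = ("inside", "outside", "unassigned")


@dataclass(frozen=True)
class LabelMask:
    """A 3D integer label image with physical voxel spacing.

    ``array`` holds one integer label per segmented object (0 = background),
    axis order (z, y, x); ``spacing`` gives µm per voxel along the same axes.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.array)
        if arr.ndim != 3:
            raise SchemaError(f"label mask must be 3D (z,y,x), got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer) and arr.dtype != bool:
            raise SchemaError(
                f"label mask must have an integer dtype, got {arr.dtype}; "
                "export segmented objects as a label image, not intensities"
            )
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise SpacingError(f"spacing must be 3 positive µm values (z,y,x), got {self.spacing}")
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        u = np.unique(self.array)
        return u[u != 0]


def read_label_mask(path: str | Path, spacing) -> LabelMask:
    """Read a multi-page TIFF label stack and attach voxel spacing.

    Spacing is a required argument: it is never guessed from TIFF metadata.
    Float-typed TIFFs are rejected with a hint to export labels.
    """
    if spacing is None:
        raise SpacingError("voxel spacing (z,y,x µm) is required and never guessed")
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if np.issubdtype(arr.dtype, np.floating):
        raise SchemaError(
            f"{path}: float-typed TIFF; label masks must be integer — "
            "re-export the segmentation as a label image"
        )
    return LabelMask(array=arr, spacing=tuple(spacing))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a multi-page TIFF, (z,y,x), 16-bit when possible."""
    arr = mask.array
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.max(initial=0) <= np.iinfo(np.uint16).max and arr.min(initial=0) >= 0:
        arr = arr.astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in REQUIRED_COLUMNS or low in FLAG_COLUMNS or low in ("compartment", "stage_label"):
            mapping[col] = low
    return df.rename(columns=mapping)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table (CSV, or TSV for ``.tsv``/``.txt`` extensions).

    Headers are matched case-insensitively; flags are coerced to bool;
    unknown columns are preserved untouched. Missing required columns raise
    :class:`~vasckinetics.errors.SchemaError` naming them.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = _normalize_columns(pd.read_csv(path, sep=sep))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            df[flag] = df[flag].astype(int).astype(bool)
    if "compartment" in df.columns:
        bad = set(df["compartment"].unique()) - set(COMPARTMENTS)
        if bad:
            raise SchemaError(f"{path}: unknown compartment labels {sorted(bad)}")
    else:
        df["compartment"] = "unassigned"
    return df


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV (TSV for ``.tsv``), flags as 0/1, lossless."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = table.copy()
    for flag in FLAG_COLUMNS:
        if flag in out.columns:
            out[flag] = out[flag].astype(int)
    out.to_csv(path, sep=sep, index=False)
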