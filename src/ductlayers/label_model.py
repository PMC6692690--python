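"""Tissue-label vocabulary, label-image I/O and ROI manifests.

The eight-class tissue vocabulary is the universal currency of the
pipeline: every raster consumed or produced downstream is a 2D grid of
codes 0..7.  Codes are zero-based in storage; the clinical enumeration
starts at 1 (background) and ends at 8 (necrosis).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "TissueLabel",
    "TissueLabelImage",
    "RoiRecord",
    "LABEL_PALETTE",
    "DIAGNOSES",
    "read_label_image",
    "write_label_image",
    "read_roi_manifest",
    "write_roi_manifest",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class TissueLabel(IntEnum):
    """The 8 tissue classes, in their canonical enumeration order."""

    BACKGROUND = 0
    NORMAL_STROMA = 1
    MALIGNANT_EPITHELIUM = 2
    BLOOD = 3
    BENIGN_EPITHELIUM = 4
    SECRETION = 5
    DESMOPLASTIC_STROMA = 6
    NECROSIS = 7

    @property
    def label_name(self) -> str:
        return self.name.lower()


N_LABELS = len(TissueLabel)

#: Fixed RGB palette used for indexed-PNG storage, one triple per code.
#: Documented bit-exactly in the README; changing it breaks stored files.
LABEL_PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 255, 255),  # 0 background
    (255, 182, 193),  # 1 normal stroma
    (178, 24, 43),    # 2 malignant epithelium
    (140, 0, 0),      # 3 blood
    (33, 102, 172),   # 4 benign epithelium
    (255, 255, 153),  # 5 secretion
    (216, 179, 101),  # 6 desmoplastic stroma
    (64, 64, 64),     # 7 necrosis
)

DIAGNOSES: tuple[str, ...] = ("benign", "atypia", "dcis", "invasive")


@dataclass(frozen=True)
class TissueLabelImage:
    """A validated 2D grid of tissue codes.

    Parameters
    ----------
    grid : ndarray of shape (height, width)
        Integer tissue codes; every value must lie in ``0..7``.
        Row-major, 0-based, origin top-left.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValidationError(
                f"label grid must be 2D with positive dims, got shape {grid.shape}"
            )
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValidationError(f"label grid must be integer, got dtype {grid.dtype}")
        bad = (grid < 0) | (grid >= N_LABELS)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"label value {int(grid[r, c])} at (row={int(r)}, col={int(c)}) "
                f"outside 0..{N_LABELS - 1}"
            )
        object.__setattr__(self, "grid", grid.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


@dataclass(frozen=True)
class RoiRecord:
    roi_id: str
    label_image_path: str
    diagnosis: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"unknown diagnosis {self.diagnosis!r}; allowed: {', '.join(DIAGNOSES)}"
            )


def _flat_palette() -> list[int]:
    flat: list[int] = []
    for rgb in LABEL_PALETTE:
        flat.extend(rgb)
    return flat


def read_label_image(path: str | Path) -> TissueLabelImage:
    """Read an indexed-PNG or single-channel-TIFF label raster.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValidationError
        If any stored value (palette index or gray value) falls
        outside ``0..7``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label image not found: {path}")
    with Image.open(path) as im:
        if im.mode not in ("P", "L", "I", "I;16"):
            raise ValidationError(
                f"{path}: unsupported image mode {im.mode!r}; expected indexed "
                "PNG (P) or single-channel TIFF (L/I)"
            )
        arr = np.asarray(im)
    return TissueLabelImage(arr.astype(np.int64))


def write_label_image(img: TissueLabelImage, path: str | Path) -> Path:
    """Write *img* so that :func:`read_label_image` round-trips bit-exactly.

    ``.png`` paths get an indexed PNG with the fixed 8-color palette;
    ``.tif``/``.tiff`` paths get an 8-bit single-channel TIFF.
    """
    if not isinstance(img, TissueLabelImage):
        img = TissueLabelImage(np.asarray(img))
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        Image.fromarray(img.grid, mode="L").save(path)
    else:
        pil = Image.fromarray(img.grid, mode="P")
        pil.putpalette(_flat_palette())
        pil.save(path, format="PNG")
    return path


def read_roi_manifest(path: str | Path) -> list[RoiRecord]:
    """Read a CSV manifest with columns roi_id, label_image_path, diagnosis.

    Diagnosis strings are normalized case-insensitively; unknown values
    raise :class:`ValidationError` listing the allowed vocabulary.
    """
    path = Path(path)
    records: list[RoiRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"roi_id", "label_image_path", "diagnosis"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            diag = row["diagnosis"].strip().lower()
            if diag not in DIAGNOSES:
                raise ValidationError(
                    f"{path} row {i + 1}: unknown diagnosis {row['diagnosis']!r}; "
                    f"allowed values: {', '.join(DIAGNOSES)}"
                )
            records.append(
                RoiRecord(
                    roi_id=row["roi_id"].strip(),
                    label_image_path=row["label_image_path"].strip(),
                    diagnosis=diag,
                )
            )
    return records


def write_roi_manifest(records: Sequence[RoiRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["roi_id", "label_image_path", "diagnosis"])
        for rec in records:
            writer.writerow([rec.roi_id, rec.label_image_path, rec.diagnosis])
    return path
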