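"""Synthetic tissue-label fixtures with category-specific duct morphology.

Rasters are rendered on a coarse cell grid (one cell = one lattice
superpixel) and upsampled, so the downstream lattice partition recovers
the intended geometry exactly.  Morphology conventions (fixture
conventions, not biological claims):

* ``benign``   — elliptical duct with a 1-cell benign-epithelium rim and
  an empty (background) lumen, in normal stroma;
* ``atypia``   — thickened 2-cell benign-epithelium rim, lumen filled
  with secretion, in normal stroma;
* ``dcis``     — duct filled with malignant epithelium, optional central
  necrosis, in normal stroma;
* ``invasive`` — irregular malignant-epithelium nests without closed
  rims, in desmoplastic stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .label_model import (
    DIAGNOSES,
    TissueLabel,
    TissueLabelImage,
    RoiRecord,
    ValidationError,
    write_label_image,
    write_roi_manifest,
)

__all__ = ["SyntheticRoiSpec", "generate_roi", "generate_dataset"]

# 4-connected structuring element, matching the pipeline's adjacency
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SyntheticRoiSpec:
    """Parameters for one synthetic ROI.

    ``rim_thickness`` is in superpixels (cells); ``duct_radius_range``
    in pixels.  ``fill_label`` is the lumen fill for benign/atypia and
    is ignored for dcis/invasive.  Fields left as ``None`` take
    category-specific defaults.
    """

    category: str
    image_size: int = 384
    superpixel_px: int = 16
    n_ducts: int = 3
    duct_radius_range: tuple[int, int] = (48, 72)
    rim_thickness: int | None = None
    fill_label: int | None = None
    stroma_label: int | None = None
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in DIAGNOSES:
            raise ValidationError(f"unknown category {self.category!r}")
        if not 0.0 <= self.noise_rate <= 0.2:
            raise ValidationError(
                f"noise_rate must be in [0, 0.2], got {self.noise_rate}"
            )
        if self.n_ducts < 1:
            raise ValidationError("n_ducts must be >= 1")
        lo, hi = self.duct_radius_range
        if not (0 < lo <= hi):
            raise ValidationError(f"bad duct_radius_range {self.duct_radius_range}")

    def resolved(self) -> "SyntheticRoiSpec":
        """Fill category defaults for rim/fill/stroma."""
        rim = self.rim_thickness
        fill = self.fill_label
        stroma = self.stroma_label
        if rim is None:
            rim = {"benign": 1, "atypia": 2, "dcis": 0, "invasive": 0}[self.category]
        if fill is None:
            fill = {
                "benign": int(TissueLabel.BACKGROUND),
                "atypia": int(TissueLabel.SECRETION),
                "dcis": int(TissueLabel.MALIGNANT_EPITHELIUM),
                "invasive": int(TissueLabel.MALIGNANT_EPITHELIUM),
            }[self.category]
        if stroma is None:
            stroma = (
                int(TissueLabel.DESMOPLASTIC_STROMA)
                if self.category == "invasive"
                else int(TissueLabel.NORMAL_STROMA)
            )
        return replace(self, rim_thickness=rim, fill_label=fill, stroma_label=stroma)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    theta: float,
) -> np.ndarray:
    rows, cols = np.indices(shape)
    dy = rows - center[0]
    dx = cols - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    ry, rx = radii
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _place_ducts(
    n_cells: int,
    n_ducts: int,
    radius_cells: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 400,
) -> list[np.ndarray]:
    """Place non-overlapping elliptical cell masks with a >= 2-cell gap."""
    occupied = np.zeros((n_cells, n_cells), dtype=bool)
    masks: list[np.ndarray] = []
    lo, hi = radius_cells
    for _ in range(n_ducts):
        placed = False
        for attempt in range(max_tries):
            # prefer the requested sizes; fall back to the small end of the
            # range once the canvas gets crowded
            r_hi = hi if attempt < max_tries // 2 else lo + 0.3 * (hi - lo)
            ry = rng.uniform(lo, max(lo, r_hi))
            rx = ry * rng.uniform(0.7, 1.3)  # randomized eccentricity
            rx = min(max(rx, lo * 0.7), hi)
            margin = max(rx, ry) + 0.5
            if 2 * margin >= n_cells:
                continue
            cy = rng.uniform(margin, n_cells - margin)
            cx = rng.uniform(margin, n_cells - margin)
            mask = _ellipse_mask((n_cells, n_cells), (cy, cx), (ry, rx), rng.uniform(0, np.pi))
            if mask.sum() < 3:
                continue
            # 1-cell gap keeps neighboring objects in separate 4-connected
            # components
            grown = ndimage.binary_dilation(mask, _CROSS, iterations=1)
            if (grown & occupied).any():
                continue
            occupied |= grown
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise ValidationError(
                "could not place all ducts at the requested density; "
                "reduce n_ducts or duct_radius_range"
            )
    return masks


def _paint_duct(cells: np.ndarray, mask: np.ndarray, spec: SyntheticRoiSpec) -> None:
    """Paint one duct's cells in place according to the category."""
    rim_epi = (
        int(TissueLabel.MALIGNANT_EPITHELIUM)
        if spec.category in ("dcis", "invasive")
        else int(TissueLabel.BENIGN_EPITHELIUM)
    )
    if spec.category in ("dcis", "invasive"):
        cells[mask] = rim_epi
        if spec.category == "dcis":
            core = ndimage.binary_erosion(mask, _CROSS, iterations=4)
            cells[core] = int(TissueLabel.NECROSIS)
        return
    interior = ndimage.binary_erosion(mask, _CROSS, iterations=spec.rim_thickness)
    cells[mask & ~interior] = rim_epi
    cells[interior] = spec.fill_label


def generate_roi(spec: SyntheticRoiSpec) -> tuple[TissueLabelImage, np.ndarray]:
    """Render one ROI; returns the label image and the ground-truth duct
    mask (pixel-level boolean, True on duct-tissue superpixel regions).

    Deterministic given ``spec.seed``.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    s = spec.superpixel_px
    n_cells = spec.image_size // s
    if n_cells < 4:
        raise ValidationError("image_size must cover at least 4x4 superpixels")

    radius_cells = (
        spec.duct_radius_range[0] / s,
        spec.duct_radius_range[1] / s,
    )
    if spec.category == "invasive":
        # irregular small nests, no closed rims
        radius_cells = (max(1.1, radius_cells[0] / 3), max(1.6, radius_cells[1] / 3))
        n_ducts = spec.n_ducts * 2
    else:
        n_ducts = spec.n_ducts

    cells = np.full((n_cells, n_cells), spec.stroma_label, dtype=np.uint8)
    masks = _place_ducts(n_cells, n_ducts, radius_cells, rng)
    for mask in masks:
        _paint_duct(cells, mask, spec)

    duct_tissue = np.isin(
        cells,
        [
            int(TissueLabel.MALIGNANT_EPITHELIUM),
            int(TissueLabel.BENIGN_EPITHELIUM),
            int(TissueLabel.SECRETION),
            int(TissueLabel.NECROSIS),
        ],
    )

    # upsample cells to pixels; the raster side is n_cells * s, i.e.
    # image_size rounded down to a whole number of superpixels
    grid = np.kron(cells, np.ones((s, s), dtype=np.uint8))
    truth = np.kron(duct_tissue, np.ones((s, s), dtype=bool))

    if spec.noise_rate > 0:
        flip = rng.random(grid.shape) < spec.noise_rate
        # flip to a uniformly random OTHER label
        offsets = rng.integers(1, 8, size=grid.shape, dtype=np.uint8)
        grid = np.where(flip, (grid + offsets) % 8, grid).astype(np.uint8)

    return TissueLabelImage(grid), truth


def generate_dataset(
    n_per_category: int,
    out_dir: str | Path,
    base_spec: SyntheticRoiSpec | None = None,
    seed: int = 0,
) -> tuple[list[RoiRecord], Path]:
    """Write ``4 * n_per_category`` label images plus a manifest CSV.

    Per-ROI seeds are derived deterministically from *seed*.  Returns
    the records and the manifest path.
    """
    if n_per_category < 1:
        raise ValidationError("n_per_category must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[RoiRecord] = []
    for ci, category in enumerate(DIAGNOSES):
        for i in range(n_per_category):
            roi_seed = seed * 1_000_003 + ci * 10_007 + i * 31
            if base_spec is not None:
                spec = replace(base_spec, category=category, seed=roi_seed)
            else:
                spec = SyntheticRoiSpec(category=category, seed=roi_seed)
            # deterministic bounded retry: a rare unlucky placement draw
            # should not abort the whole dataset
            for bump in range(20):
                try:
                    img, _ = generate_roi(replace(spec, seed=spec.seed + bump))
                    break
                except ValidationError:
                    continue
            else:
                raise ValidationError(
                    f"could not generate ROI for {category} at seed {roi_seed}; "
                    "reduce n_ducts or duct_radius_range"
                )
            roi_id = f"{category}_{i:03d}"
            fname = f"{roi_id}.png"
            write_label_image(img, out_dir / fname)
            records.append(
                RoiRecord(roi_id=roi_id, label_image_path=fname, diagnosis=category)
            )
    manifest = write_roi_manifest(records, out_dir / "manifest.csv")
    return records, manifest
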