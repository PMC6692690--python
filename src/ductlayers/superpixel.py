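"""Superpixel partitions of an ROI: lattice or SLIC backends, majority
tissue labels, and the 4-connected region adjacency graph."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from skimage.segmentation import slic

from .label_model import N_LABELS, TissueLabelImage, ValidationError

__all__ = [
    "SuperpixelPartition",
    "lattice_superpixels",
    "color_superpixels",
    "assign_majority_labels",
    "build_adjacency",
    "make_partition",
]

logger = logging.getLogger(__name__)

DEFAULT_TARGET_AREA = 3000  # px; chosen to cover at least one epithelial cell
DEFAULT_COMPACTNESS = 10.0


@dataclass(frozen=True)
class SuperpixelPartition:
    """A partition of the pixel grid into K superpixels.

    Attributes
    ----------
    assignment : ndarray (H, W) of int
        Superpixel id per pixel, ids contiguous in ``0..K-1``.
    sizes : ndarray (K,) of int
        Pixel count per id.
    majority_label : ndarray (K,) of int or None
        Modal tissue code per superpixel (ties -> lowest code), or
        ``None`` before :func:`assign_majority_labels` is applied.
    adjacency : networkx.Graph or None
        Undirected graph on ids; edge (a, b) iff some pixel of a is
        4-connected to some pixel of b.  ``None`` until built.
    """

    assignment: np.ndarray
    sizes: np.ndarray
    majority_label: np.ndarray | None = None
    adjacency: nx.Graph | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment)
        if a.ndim != 2:
            raise ValidationError(f"assignment must be 2D, got shape {a.shape}")
        ids = np.unique(a)
        k = len(ids)
        if not np.array_equal(ids, np.arange(k)):
            raise ValidationError("superpixel ids must be contiguous 0..K-1")
        sizes = np.asarray(self.sizes)
        if sizes.shape != (k,) or int(sizes.sum()) != a.size:
            raise ValidationError("sizes must be per-id counts summing to H*W")

    @property
    def n_superpixels(self) -> int:
        return len(self.sizes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.assignment.shape


def _relabel_contiguous(assignment: np.ndarray) -> np.ndarray:
    _, inv = np.unique(assignment, return_inverse=True)
    return inv.reshape(assignment.shape)


def _partition_from_assignment(assignment: np.ndarray) -> SuperpixelPartition:
    assignment = _relabel_contiguous(assignment)
    sizes = np.bincount(assignment.ravel())
    return SuperpixelPartition(assignment=assignment, sizes=sizes)


def lattice_superpixels(
    img: TissueLabelImage, target_area: int = DEFAULT_TARGET_AREA
) -> SuperpixelPartition:
    """Deterministic axis-aligned tiling into tiles of side ``floor(sqrt(target_area))``.

    Edge tiles may be smaller.  Stand-in for color-based superpixels when
    only a label raster is available (synthetic fixtures have no color).
    """
    if target_area < 1:
        raise ValidationError(f"target_area must be >= 1, got {target_area}")
    h, w = img.height, img.width
    if target_area > h * w:
        logger.warning(
            "target_area %d exceeds image area %d; using a single superpixel",
            target_area,
            h * w,
        )
        return _partition_from_assignment(np.zeros((h, w), dtype=np.int64))
    side = max(1, math.floor(math.sqrt(target_area)))
    rows = np.arange(h) // side
    cols = np.arange(w) // side
    n_tile_cols = math.ceil(w / side)
    assignment = rows[:, None] * n_tile_cols + cols[None, :]
    return _partition_from_assignment(assignment)


def color_superpixels(
    rgb: np.ndarray,
    target_area: int = DEFAULT_TARGET_AREA,
    compactness: float = DEFAULT_COMPACTNESS,
    label_shape: tuple[int, int] | None = None,
) -> SuperpixelPartition:
    """SLIC superpixels of roughly *target_area* pixels on an RGB raster.

    *label_shape*, if given, is the shape of the paired label image and
    must match the raster dimensions.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError(f"expected (H, W, 3) RGB raster, got shape {rgb.shape}")
    h, w = rgb.shape[:2]
    if label_shape is not None and tuple(label_shape) != (h, w):
        raise ValidationError(
            f"RGB raster shape {(h, w)} does not match label image shape {tuple(label_shape)}"
        )
    n_segments = max(1, round(h * w / target_area))
    seg = slic(
        rgb,
        n_segments=n_segments,
        compactness=compactness,
        start_label=0,
        enforce_connectivity=True,
        channel_axis=-1,
    )
    return _partition_from_assignment(seg)


def assign_majority_labels(
    part: SuperpixelPartition, img: TissueLabelImage
) -> SuperpixelPartition:
    """Assign each superpixel the modal tissue code of its pixels.

    Ties break toward the lowest code (determinism; ``bincount`` +
    ``argmax`` guarantees this).
    """
    if part.shape != (img.height, img.width):
        raise ValidationError(
            f"assignment shape {part.shape} != label grid shape "
            f"{(img.height, img.width)}"
        )
    k = part.n_superpixels
    flat_ids = part.assignment.ravel().astype(np.int64)
    flat_labels = img.grid.ravel().astype(np.int64)
    # joint histogram of (superpixel, label), K x 8
    joint = np.bincount(flat_ids * N_LABELS + flat_labels, minlength=k * N_LABELS)
    joint = joint.reshape(k, N_LABELS)
    majority = joint.argmax(axis=1).astype(np.uint8)
    return replace(part, majority_label=majority)


def build_adjacency(part: SuperpixelPartition) -> SuperpixelPartition:
    """Build the 4-connected region adjacency graph over superpixel ids."""
    a = part.assignment
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(part.n_superpixels))
    horiz = np.stack([a[:, :-1].ravel(), a[:, 1:].ravel()], axis=1)
    vert = np.stack([a[:-1, :].ravel(), a[1:, :].ravel()], axis=1)
    pairs = np.concatenate([horiz, vert], axis=0)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    g.add_edges_from(map(tuple, edges))
    return replace(part, adjacency=g)


def make_partition(
    img: TissueLabelImage,
    target_area: int = DEFAULT_TARGET_AREA,
    rgb: np.ndarray | None = None,
    compactness: float = DEFAULT_COMPACTNESS,
) -> SuperpixelPartition:
    """Convenience constructor: partition, majority labels and adjacency.

    Uses the SLIC backend when an RGB raster is supplied, the lattice
    backend otherwise.
    """
    if rgb is not None:
        part = color_superpixels(
            rgb, target_area, compactness, label_shape=(img.height, img.width)
        )
    else:
        part = lattice_superpixels(img, target_area)
    part = assign_majority_labels(part, img)
    return build_adjacency(part)
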