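"""Shared fixtures and independent oracles.

The layer-peeling oracle here works on boolean cell arrays with
scipy.ndimage erosion/dilation — deliberately independent of the
package's graph-based implementation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ductlayers.label_model import TissueLabelImage
from ductlayers.superpixel import (
    assign_majority_labels,
    build_adjacency,
    lattice_superpixels,
)

CROSS = ndimage.generate_binary_structure(2, 1)


def cell_partition(label_grid: np.ndarray):
    """Partition with one superpixel per cell: id = row * W + col."""
    img = TissueLabelImage(np.asarray(label_grid, dtype=np.int64))
    part = lattice_superpixels(img, target_area=1)
    part = assign_majority_labels(part, img)
    return build_adjacency(part)


def oracle_peel(mask: np.ndarray, n_inner: int = 5, n_outer: int = 5):
    """Brute-force layer peeling by iterated set erosion/dilation.

    Cells outside the raster count as members for erosion (the graph has
    no nodes there), so border members are not peeled from the image
    edge.  Returns (inner, outer) as lists of boolean arrays; inner[0]
    is the boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    inner = []
    cur = mask
    for _ in range(n_inner):
        eroded = ndimage.binary_erosion(cur, CROSS, border_value=1)
        inner.append(cur & ~eroded)
        cur = eroded
    outer = []
    cur = mask
    for _ in range(n_outer):
        dilated = ndimage.binary_dilation(cur, CROSS)
        outer.append(dilated & ~cur)
        cur = dilated
    return inner, outer


def mask_to_ids(mask: np.ndarray) -> frozenset[int]:
    """Cell mask -> superpixel ids under the cell_partition convention."""
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    return frozenset(int(r) * w + int(c) for r, c in zip(rows, cols))


def random_blob(shape: tuple[int, int], size: int, rng: np.random.Generator) -> np.ndarray:
    """Connected random blob grown from a seed cell by neighbor accretion."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    start = (int(rng.integers(h)), int(rng.integers(w)))
    mask[start] = True
    frontier = {start}
    while mask.sum() < size and frontier:
        candidates = sorted(
            {
                (r + dr, c + dc)
                for (r, c) in frontier
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < h and 0 <= c + dc < w and not mask[r + dr, c + dc]
            }
        )
        if not candidates:
            break
        pick = candidates[rng.integers(len(candidates))]
        mask[pick] = True
        frontier.add(pick)
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
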