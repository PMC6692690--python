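"""The structure feature: onion layers around duct objects.

For each duct, 5 layers are peeled toward the inside (iterated boundary
removal, i.e. erosion depth in the adjacency graph) and 5 toward the
outside (graph distance from the member set).  Each layer yields a
normalized 8-bin tissue histogram of its superpixels' majority labels; a
duct therefore contributes a 10 x 8 histogram stack.  Duct stacks are
aggregated per ROI by summing raw counts layer-wise and renormalizing,
so the feature is dominated by the largest structures, then flattened
row-major into an 80-dim vector.

Layer row order is fixed: inner5, inner4, ..., inner1, outer1, ..., outer5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ducts import DuctObject
from .label_model import N_LABELS
from .superpixel import SuperpixelPartition

__all__ = [
    "N_INNER",
    "N_OUTER",
    "N_LAYERS",
    "FEATURE_LENGTH",
    "LAYER_NAMES",
    "LayerAssignment",
    "LayerHistogramStack",
    "StructureFeature",
    "peel_layers",
    "layer_histograms",
    "roi_structure_feature",
    "feature_column_names",
]

logger = logging.getLogger(__name__)

N_INNER = 5
N_OUTER = 5
N_LAYERS = N_INNER + N_OUTER
FEATURE_LENGTH = N_LAYERS * N_LABELS

#: Row order of the histogram stack: inner5..inner1 then outer1..outer5.
LAYER_NAMES: tuple[str, ...] = tuple(
    f"layer{k:+d}" for k in list(range(-N_INNER, 0)) + list(range(1, N_OUTER + 1))
)


@dataclass(frozen=True)
class LayerAssignment:
    """Per-duct layer sets.

    ``inner[k-1]`` holds the members at erosion depth k (k = 1 is the
    boundary); ``outer[k-1]`` holds the non-members at graph distance k
    from the member set.  All 10 sets are pairwise disjoint; inner sets
    are subsets of the duct, outer sets are disjoint from it.
    """

    duct_id: int
    inner: tuple[frozenset[int], ...]
    outer: tuple[frozenset[int], ...]

    def layer_sets(self) -> tuple[frozenset[int], ...]:
        """The 10 sets in canonical row order (inner5..inner1, outer1..outer5)."""
        return tuple(reversed(self.inner)) + self.outer


@dataclass(frozen=True)
class LayerHistogramStack:
    """10 x 8 per-layer tissue histograms for one duct."""

    counts: np.ndarray  # (10, 8) int
    duct_id: int = -1

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_LAYERS, N_LABELS):
            raise ValueError(
                f"counts must be {(N_LAYERS, N_LABELS)}, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def normalized(self) -> np.ndarray:
        """Row-stochastic matrix; all-zero rows stay all-zero."""
        return _normalize_rows(self.counts.astype(float))


@dataclass(frozen=True)
class StructureFeature:
    """The flattened 80-dim ROI structure feature."""

    vector: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.shape != (FEATURE_LENGTH,):
            raise ValueError(f"vector must have length {FEATURE_LENGTH}, got {vec.shape}")
        object.__setattr__(self, "vector", vec)

    @property
    def stack(self) -> np.ndarray:
        return self.vector.reshape(N_LAYERS, N_LABELS)


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=1, keepdims=True)
    out = np.zeros_like(mat, dtype=float)
    np.divide(mat, sums, out=out, where=sums > 0)
    return out


def peel_layers(
    duct: DuctObject,
    adjacency: nx.Graph,
    n_inner: int = N_INNER,
    n_outer: int = N_OUTER,
) -> LayerAssignment:
    """Peel one-superpixel-thick layers inward and outward from a duct.

    Inner layer k is found by iteratively removing the current boundary
    (members adjacent to at least one node outside the remaining set);
    this equals the set of members at graph distance k from the
    complement.  Outer layer k is the set of non-members at graph
    distance k from the member set.  Members deeper than *n_inner* and
    non-members farther than *n_outer* are left unassigned.
    """
    members = set(duct.member_ids)
    if not members <= set(adjacency.nodes):
        raise ValueError("duct members must be nodes of the adjacency graph")

    inner: list[frozenset[int]] = []
    remaining = set(members)
    for _ in range(n_inner):
        if not remaining:
            inner.append(frozenset())
            continue
        boundary = {
            u
            for u in remaining
            if any(v not in remaining for v in adjacency.neighbors(u))
        }
        # a remaining set with no exterior neighbors (duct covers a whole
        # graph component) has no boundary; its erosion depth is infinite
        inner.append(frozenset(boundary))
        remaining -= boundary

    outer: list[frozenset[int]] = []
    frontier = set(members)
    visited = set(members)
    for _ in range(n_outer):
        nxt = {
            v
            for u in frontier
            for v in adjacency.neighbors(u)
            if v not in visited
        }
        outer.append(frozenset(nxt))
        visited |= nxt
        frontier = nxt

    return LayerAssignment(duct_id=duct.duct_id, inner=tuple(inner), outer=tuple(outer))


def layer_histograms(
    assignment: LayerAssignment, part: SuperpixelPartition
) -> LayerHistogramStack:
    """Count superpixels per (layer, majority label) for one duct."""
    if part.majority_label is None:
        raise ValueError("majority labels must be assigned before layer histograms")
    counts = np.zeros((N_LAYERS, N_LABELS), dtype=np.int64)
    for row, ids in enumerate(assignment.layer_sets()):
        for sp in ids:
            counts[row, int(part.majority_label[sp])] += 1
    return LayerHistogramStack(counts=counts, duct_id=assignment.duct_id)


def roi_structure_feature(
    stacks: list[LayerHistogramStack],
    roi_id: str = "",
    sum_counts: bool = True,
) -> StructureFeature:
    """Aggregate duct stacks into one ROI feature.

    With ``sum_counts=True`` (default) raw counts are summed layer-wise
    across ducts before normalizing, so large structures dominate.  With
    ``sum_counts=False`` each duct's normalized stack is summed instead
    (equal per-duct weight) and then renormalized.
    """
    if not stacks:
        logger.warning("ROI %s has no duct objects; structure feature is all-zero", roi_id)
        return StructureFeature(np.zeros(FEATURE_LENGTH), roi_id=roi_id)
    if sum_counts:
        total = np.sum([s.counts for s in stacks], axis=0).astype(float)
    else:
        total = np.sum([s.normalized for s in stacks], axis=0)
    return StructureFeature(_normalize_rows(total).ravel(), roi_id=roi_id)


def feature_column_names() -> list[str]:
    """Column names for the 80 feature entries: ``layer{-5..-1,+1..+5}_label{0..7}``."""
    return [
        f"{layer}_label{code}" for layer in LAYER_NAMES for code in range(N_LABELS)
    ]
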