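"""Detection of objects of interest (ducts, duct groups, tumor masses).

An object is a connected component — in the superpixel adjacency graph —
of superpixels whose majority label is epithelium (benign or malignant),
secretion, or necrosis.  Components smaller than ``min_size`` superpixels
are discarded as cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .label_model import TissueLabel, ValidationError
from .superpixel import SuperpixelPartition

__all__ = ["DuctObject", "DUCT_LABELS", "duct_mask", "find_objects", "detect_ducts"]

#: Majority labels that constitute duct tissue.
DUCT_LABELS = frozenset(
    {
        int(TissueLabel.MALIGNANT_EPITHELIUM),
        int(TissueLabel.BENIGN_EPITHELIUM),
        int(TissueLabel.SECRETION),
        int(TissueLabel.NECROSIS),
    }
)

DEFAULT_MIN_SIZE = 3


@dataclass(frozen=True)
class DuctObject:
    duct_id: int
    member_ids: frozenset[int]

    @property
    def size_superpixels(self) -> int:
        return len(self.member_ids)


def duct_mask(part: SuperpixelPartition) -> set[int]:
    """Superpixel ids whose majority label is duct tissue."""
    if part.majority_label is None:
        raise ValidationError("majority labels must be assigned before duct masking")
    return {
        int(i) for i, lab in enumerate(part.majority_label) if int(lab) in DUCT_LABELS
    }


def find_objects(
    mask: set[int], adjacency: nx.Graph, min_size: int = DEFAULT_MIN_SIZE
) -> list[DuctObject]:
    """Connected components of the mask-induced subgraph, cleaned and ordered.

    Components with fewer than *min_size* superpixels are removed.  The
    survivors are ordered by decreasing size, ties broken by smallest
    member id, and assigned duct_ids 0, 1, ... in that order.
    """
    if min_size < 1:
        raise ValidationError(f"min_size must be >= 1, got {min_size}")
    if not set(mask) <= set(adjacency.nodes):
        raise ValidationError("mask contains ids absent from the adjacency graph")
    sub = adjacency.subgraph(mask)
    comps = [frozenset(c) for c in nx.connected_components(sub)]
    comps = [c for c in comps if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [DuctObject(duct_id=i, member_ids=c) for i, c in enumerate(comps)]


def detect_ducts(
    part: SuperpixelPartition, min_size: int = DEFAULT_MIN_SIZE
) -> list[DuctObject]:
    """duct_mask + find_objects on a fully-built partition."""
    if part.adjacency is None:
        raise ValidationError("adjacency graph must be built before duct detection")
    return find_objects(duct_mask(part), part.adjacency, min_size=min_size)
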