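"""Tissue distribution feature: superpixel label frequencies plus label
co-occurrence over the adjacency graph (36 unordered pairs incl. diagonal,
edge-normalized; a 64-bin directed variant is available behind a flag)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import N_LABELS, ValidationError
from .superpixel import SuperpixelPartition

__all__ = [
    "TissueDistributionFeature",
    "tissue_frequency",
    "tissue_cooccurrence",
    "roi_distribution_feature",
    "distribution_column_names",
    "N_PAIRS",
]

#: Unordered label pairs (a, b), a <= b, in stable column order.
PAIRS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(N_LABELS) for b in range(a, N_LABELS)
)
N_PAIRS = len(PAIRS)  # 36
_PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}


@dataclass(frozen=True)
class TissueDistributionFeature:
    frequency: np.ndarray  # (8,)
    cooccurrence: np.ndarray  # (36,) or (64,) for the directed variant
    roi_id: str = ""

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.frequency, self.cooccurrence])


def tissue_frequency(part: SuperpixelPartition) -> np.ndarray:
    """Fraction of superpixels carrying each tissue code; sums to 1."""
    if part.majority_label is None:
        raise ValidationError("majority labels must be assigned")
    k = part.n_superpixels
    if k == 0:
        raise ValidationError("empty partition")
    return np.bincount(part.majority_label, minlength=N_LABELS) / k


def tissue_cooccurrence(
    part: SuperpixelPartition, directed: bool = False
) -> np.ndarray:
    """Label co-occurrence histogram over adjacency edges.

    Symmetric by default: each edge increments its unordered label pair
    (36 bins, diagonal included), normalized by edge count.  With
    ``directed=True`` each edge increments both ordered pairs of an
    8 x 8 matrix, flattened to 64 bins.  Graphs with no edges yield the
    all-zero vector.
    """
    if part.majority_label is None:
        raise ValidationError("majority labels must be assigned")
    if part.adjacency is None:
        raise ValidationError("adjacency graph must be built")
    labels = part.majority_label
    if directed:
        hist = np.zeros((N_LABELS, N_LABELS))
        for u, v in part.adjacency.edges:
            a, b = int(labels[u]), int(labels[v])
            hist[a, b] += 1
            hist[b, a] += 1
        total = hist.sum()
        return (hist / total if total > 0 else hist).ravel()
    hist = np.zeros(N_PAIRS)
    n_edges = part.adjacency.number_of_edges()
    for u, v in part.adjacency.edges:
        a, b = sorted((int(labels[u]), int(labels[v])))
        hist[_PAIR_INDEX[(a, b)]] += 1
    return hist / n_edges if n_edges > 0 else hist


def roi_distribution_feature(
    part: SuperpixelPartition, roi_id: str = "", directed: bool = False
) -> TissueDistributionFeature:
    """Concatenate frequency (8) and co-occurrence (36) into one feature."""
    return TissueDistributionFeature(
        frequency=tissue_frequency(part),
        cooccurrence=tissue_cooccurrence(part, directed=directed),
        roi_id=roi_id,
    )


def distribution_column_names(directed: bool = False) -> list[str]:
    names = [f"freq_label{c}" for c in range(N_LABELS)]
    if directed:
        names += [f"cooc_{a}_{b}" for a in range(N_LABELS) for b in range(N_LABELS)]
    else:
        names += [f"cooc_{a}_{b}" for a, b in PAIRS]
    return names
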