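"""External validation of partitions: adjusted Rand index, purity, entropy."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PartitionPair", "contingency_table", "adjusted_rand_index", "purity", "entropy"]


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """Co-occurrence counts between two partitions of the same samples."""
    a, b = _encode(labels_a), _encode(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same samples")
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


@dataclass
class PartitionPair:
    labels_a: np.ndarray
    labels_b: np.ndarray

    def __post_init__(self) -> None:
        self.labels_a = np.asarray(self.labels_a)
        self.labels_b = np.asarray(self.labels_b)
        if len(self.labels_a) != len(self.labels_b):
            raise ValueError("partitions have different lengths")

    @property
    def contingency(self) -> np.ndarray:
        return contingency_table(self.labels_a, self.labels_b)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (Hubert-Arabie).

    ARI = (sum_ij C(n_ij,2) - E) / (0.5 [sum_i C(a_i,2) + sum_j C(b_j,2)] - E)
    with E the product of the marginal pair counts over C(n,2).  Symmetric
    and invariant to relabeling.  When the denominator degenerates (both
    partitions all singletons, or both one block) the result is 1 for
    identical partitions and 0 otherwise, with a warning.
    """
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least two samples")
    sum_ij = _comb2(table.astype(float)).sum()
    a = _comb2(table.sum(axis=1).astype(float)).sum()
    b = _comb2(table.sum(axis=0).astype(float)).sum()
    total = _comb2(float(n))
    expected = a * b / total
    denom = 0.5 * (a + b) - expected
    if denom == 0.0:
        identical = (np.count_nonzero(table, axis=0) <= 1).all() and (
            np.count_nonzero(table, axis=1) <= 1
        ).all()
        logger.warning("degenerate ARI denominator; returning %d", int(identical))
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / denom)


def purity(predicted, truth) -> float:
    """Fraction of samples in the majority true class of their predicted
    cluster, summed over clusters: (1/n) sum_c max_t n_ct."""
    table = contingency_table(predicted, truth)
    return float(table.max(axis=1).sum() / table.sum())


def entropy(predicted, truth, normalize: bool = True) -> float:
    """Size-weighted mean entropy (bits) of true classes within each
    predicted cluster; by default divided by log2(#true classes) so the
    value lies in [0, 1].  0 log 0 is taken as 0."""
    table = contingency_table(predicted, truth).astype(float)
    n = table.sum()
    n_true = table.shape[1]
    if n_true < 2:
        return 0.0
    sizes = table.sum(axis=1)
    ent = 0.0
    for c in range(table.shape[0]):
        if sizes[c] == 0:
            continue
        p = table[c] / sizes[c]
        nz = p > 0
        ent += (sizes[c] / n) * float(-(p[nz] * np.log2(p[nz])).sum())
    if normalize:
        ent /= np.log2(n_true)
    return float(ent)
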