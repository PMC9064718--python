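"""Cluster validity indices and contingency-table association.

External indices (adjusted Rand, Fowlkes–Mallows, purity) score a
clustering against known class labels; all three are invariant to
renaming the labels on either side.  Internal indices (average
silhouette, Dunn) assess a flat clustering from the distance matrix
alone.  A Pearson chi-square on the cross-tabulation of two label
vectors quantifies association between two clusterings.

Purity of an all-singleton clustering is 1 by definition (every cluster
trivially pure), which can overstate quality — one reason to report the
triplet of external indices together rather than any single one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "ContingencyTable",
    "cross_tabulate",
    "adjusted_rand",
    "fowlkes_mallows",
    "purity",
    "silhouette_avg",
    "dunn_index",
    "chi_square",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of two label vectors (rows × columns)."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"({len(self.row_labels)}, {len(self.col_labels)}) labels"
            )
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        c.setflags(write=False)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"label vectors must be equal-length 1-D, got {a.shape} and {b.shape}"
        )
    return a, b


def cross_tabulate(a, b) -> ContingencyTable:
    """Contingency table of two label vectors; row/column order is order of
    first appearance."""
    a, b = _check_pair(a, b)
    rows = list(dict.fromkeys(a.tolist()))
    cols = list(dict.fromkeys(b.tolist()))
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: i for i, lab in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for x, y in zip(a.tolist(), b.tolist()):
        counts[ri[x], ci[y]] += 1
    return ContingencyTable(
        row_labels=tuple(rows), col_labels=tuple(cols), counts=counts
    )


def _comb2(x: np.ndarray) -> np.ndarray:
    x = x.astype(float)
    return x * (x - 1.0) / 2.0


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index: pair-counting agreement corrected for chance
    under the generalized hypergeometric model.

    ARI = (Σ_ij C(n_ij,2) − E) / (M − E) with
    E = Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2) and
    M = ½ [Σ_i C(a_i,2) + Σ_j C(b_j,2)].  Returns 0 in the degenerate
    case M = E (e.g. both partitions all-singletons).
    """
    a, b = _check_pair(a, b)
    t = cross_tabulate(a, b)
    n = t.total
    if n < 2:
        return 0.0
    sum_ij = _comb2(t.counts.astype(float)).sum()
    sum_a = _comb2(t.counts.sum(axis=1)).sum()
    sum_b = _comb2(t.counts.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(np.array([n]))[0]
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


def fowlkes_mallows(a, b) -> float:
    """Fowlkes–Mallows index: the geometric mean of pairwise precision and
    recall, TP / sqrt((TP+FP)(TP+FN)) over co-membership pairs; 0 when the
    denominator vanishes."""
    a, b = _check_pair(a, b)
    t = cross_tabulate(a, b)
    tp = _comb2(t.counts.astype(float)).sum()
    pairs_a = _comb2(t.counts.sum(axis=1)).sum()
    pairs_b = _comb2(t.counts.sum(axis=0)).sum()
    denom = np.sqrt(pairs_a * pairs_b)
    if denom == 0.0:
        return 0.0
    return float(tp / denom)


def purity(clusters, truth) -> float:
    """Mean fraction of each cluster belonging to its majority true class:
    (1/N) Σ_clusters max_class overlap.  All-singleton clusterings score 1."""
    clusters, truth = _check_pair(clusters, truth)
    t = cross_tabulate(clusters, truth)
    if t.total == 0:
        raise ValueError("purity undefined for empty label vectors")
    return float(t.counts.max(axis=1).sum() / t.total)


def _groups(labels) -> dict:
    labels = np.asarray(labels)
    return {
        lab: np.flatnonzero(labels == lab)
        for lab in dict.fromkeys(labels.tolist())
    }


def silhouette_avg(d: DistanceMatrix, labels) -> float:
    """Average silhouette width on a precomputed distance matrix.

    Per point: s = (b − a) / max(a, b) with a the mean distance to its own
    cluster (excluding itself) and b the smallest mean distance to another
    cluster; points in singleton clusters score 0.  Requires ≥ 2 clusters.
    """
    labels = np.asarray(labels)
    if len(labels) != len(d):
        raise ValueError("labels must align with the distance matrix")
    groups = _groups(labels)
    if len(groups) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    m = d.matrix
    scores = np.zeros(len(labels))
    for lab, idx in groups.items():
        for i in idx:
            if len(idx) == 1:
                scores[i] = 0.0
                continue
            a = m[i, idx].sum() / (len(idx) - 1)
            b = min(
                m[i, jdx].mean()
                for other, jdx in groups.items()
                if other != lab
            )
            scores[i] = 0.0 if max(a, b) == 0.0 else (b - a) / max(a, b)
    return float(scores.mean())


def dunn_index(d: DistanceMatrix, labels) -> float:
    """Dunn index: minimum between-cluster separation (smallest cross-pair
    distance over all cluster pairs) divided by maximum cluster diameter
    (largest intra-pair distance).  Returns +inf when every cluster is a
    singleton (zero diameter).  Requires ≥ 2 clusters."""
    labels = np.asarray(labels)
    if len(labels) != len(d):
        raise ValueError("labels must align with the distance matrix")
    groups = list(_groups(labels).values())
    if len(groups) < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    m = d.matrix
    separation = min(
        m[np.ix_(gi, gj)].min()
        for x, gi in enumerate(groups)
        for gj in groups[x + 1 :]
    )
    diameter = max(
        m[np.ix_(g, g)].max() if len(g) > 1 else 0.0 for g in groups
    )
    if diameter == 0.0:
        return float("inf")
    return float(separation / diameter)


def chi_square(t: ContingencyTable) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom for a
    contingency table (no continuity correction).

    E_ij = (row_i total)(col_j total)/N; statistic = Σ (O−E)²/E;
    df = (r−1)(c−1).  Raises if any row or column total is zero.
    """
    counts = t.counts.astype(float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined with a zero row/column margin")
    expected = np.outer(row, col) / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (len(row) - 1) * (len(col) - 1)
    return stat, df
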