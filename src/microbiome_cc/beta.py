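"""Kullback-Leibler and Jensen-Shannon divergences, pairwise divergence
matrices, and hierarchical community clustering.

For compositions :math:`P^i = (p^i_1, ..., p^i_K)` the K-L divergence is

.. math:: D_{KL}(P^i \\| P^j) = \\sum_k p^i_k \\log(p^i_k / p^j_k)

with :math:`0 \\log(0/q) = 0`, and the (symmetric, bounded) J-S divergence is

.. math:: JSD(P^i, P^j) = \\tfrac12 D_{KL}(P^i \\| Q) + \\tfrac12 D_{KL}(P^j \\| Q),
          \\qquad Q = (P^i + P^j)/2.

Natural log is used throughout by default, so :math:`0 \\le JSD \\le \\ln 2`.
Hierarchical clustering is agglomerative (average linkage on raw JSD by
default; Ward on :math:`\\sqrt{JSD}`, which is a metric, by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .table import TaxonTable

__all__ = [
    "kl_divergence",
    "js_divergence",
    "divergence_matrix",
    "DivergenceMatrix",
    "ClusterAssignment",
    "hierarchical_clusters",
    "linkage_to_newick",
]


def _check_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if p.min() < 0 or q.min() < 0:
        raise ValueError("proportions must be non-negative")
    if not (np.isclose(p.sum(), 1.0, atol=1e-8) and np.isclose(q.sum(), 1.0, atol=1e-8)):
        raise ValueError("proportions must sum to 1")
    return p, q


def kl_divergence(p, q, base: float | None = None) -> float:
    """K-L divergence of ``p`` from ``q`` (sum over the support of ``p``).

    Returns ``inf`` when ``p`` puts mass where ``q`` has none.
    """
    p, q = _check_pair(p, q)
    support = p > 0
    if (q[support] == 0).any():
        return float("inf")
    d = float((p[support] * np.log(p[support] / q[support])).sum())
    if base is not None:
        d /= np.log(base)
    return d


def js_divergence(p, q, base: float | None = None) -> float:
    """Jensen-Shannon divergence: mean K-L of each composition from their
    midpoint.  Always finite, symmetric, and at most ln 2 (log-base 2: 1)."""
    p, q = _check_pair(p, q)
    m = 0.5 * (p + q)
    return 0.5 * (kl_divergence(p, m, base=base) + kl_divergence(q, m, base=base))


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise J-S divergence matrix over samples at one level."""

    sample_ids: list[str]
    values: np.ndarray
    level: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} samples")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("matrix must be symmetric")
        if v.size and (v.min() < -1e-12 or v.max() > np.log(2) + 1e-9):
            raise ValueError("J-S divergences must lie in [0, ln 2]")
        self.values = np.clip(v, 0.0, np.log(2))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def submatrix_mean(self, sample_idx) -> float:
        """Mean pairwise divergence among the given sample indices."""
        idx = np.asarray(sample_idx)
        sub = self.values[np.ix_(idx, idx)]
        k = len(idx)
        if k < 2:
            raise ValueError("need at least two samples")
        return float(sub.sum() / (k * (k - 1)))


def divergence_matrix(table: TaxonTable, level: str = "", base: float | None = None) -> DivergenceMatrix:
    """All pairwise J-S divergences between the samples of a relative table.

    The computation follows the two K-L terms against the pairwise midpoint,
    vectorised one row at a time.
    """
    if table.mode != "relative":
        raise ValueError("divergence_matrix requires a relative-mode table")
    P = table.data.to_numpy(dtype=float)
    n = P.shape[0]
    if n and (P.sum(axis=1) <= 0).any():
        bad = [table.sample_ids[i] for i in np.where(P.sum(axis=1) <= 0)[0]]
        raise ValueError(f"samples with all-zero composition: {bad}")
    D = np.zeros((n, n))
    log_scale = np.log(base) if base is not None else 1.0
    for i in range(n - 1):
        pi = P[i]
        pj = P[i + 1 :]
        m = 0.5 * (pi + pj)
        with np.errstate(divide="ignore", invalid="ignore"):
            ti = np.where(pi > 0, pi * np.log(np.where(pi > 0, pi / m, 1.0)), 0.0)
            tj = np.where(pj > 0, pj * np.log(np.where(pj > 0, pj / m, 1.0)), 0.0)
        row = 0.5 * (ti.sum(axis=1) + tj.sum(axis=1)) / log_scale
        D[i, i + 1 :] = row
        D[i + 1 :, i] = row
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, None)
    return DivergenceMatrix(list(table.sample_ids), D, level=level)


@dataclass
class ClusterAssignment:
    """Sample -> cluster-letter partition from cutting a dendrogram at K."""

    labels: pd.Series
    method: str
    k: int
    linkage: np.ndarray

    def counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hierarchical_clusters(
    D: DivergenceMatrix,
    k: int,
    method: str = "average",
    sqrt_transform: bool = False,
) -> ClusterAssignment:
    """Agglomerative clustering on a divergence matrix, cut to exactly ``k``.

    ``method`` is any scipy linkage method; ``sqrt_transform`` clusters on
    sqrt(JSD) (a metric), the natural companion to Ward linkage.  Clusters
    are labelled A, B, C, ... in order of first appearance in sample order.
    """
    n = D.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    cond = D.condensed()
    if sqrt_transform:
        cond = np.sqrt(cond)
    Z = hierarchy.linkage(cond, method=method)
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    letters: dict[int, str] = {}
    for c in flat:
        if c not in letters:
            letters[c] = chr(ord("A") + len(letters))
    labels = pd.Series([letters[c] for c in flat], index=D.sample_ids, name="cluster")
    return ClusterAssignment(labels, method=method, k=k, linkage=Z)


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Export a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.10g}"

    body = recurse(tree, tree.dist)
    # strip the root's zero-length suffix
    return body.rsplit(":", 1)[0] + ";"
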