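"""Within-sample (alpha) diversity estimators.

Implements richness, Shannon entropy, bias-corrected Chao1 and inverse
Simpson directly; Faith's phylogenetic diversity (the "whole tree" variant,
root connection included) is computed through scikit-bio against a rooted
newick tree.  Shannon defaults to natural log (nats); pass ``base=2`` for
the bit-based convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .table import TaxonTable

__all__ = [
    "richness",
    "shannon",
    "chao1",
    "inverse_simpson",
    "faith_pd",
    "read_tree",
    "alpha_diversity_table",
]


def richness(counts) -> int:
    """Number of taxa with abundance > 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValueError("negative abundances")
    return int((counts > 0).sum())


def shannon(proportions, base: float | None = None) -> float:
    """Shannon entropy -sum p*log(p); natural log unless ``base`` given."""
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1)/(2*(F2+1)).

    Defined for integer counts only (singletons/doubletons are meaningless
    on proportions).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValueError("negative counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("Chao1 requires integer counts, not proportions")
    counts = np.round(counts).astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def inverse_simpson(proportions) -> float:
    """Inverse Simpson concentration 1 / sum p^2."""
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("proportions must sum to 1")
    return float(1.0 / (p**2).sum())


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree with branch lengths."""
    return skbio.TreeNode.read(str(path), format="newick")


def faith_pd(present_taxa, tree: skbio.TreeNode) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning ``present_taxa`` (whole-tree variant, root path included)."""
    present = list(present_taxa)
    leaves = {leaf.name for leaf in tree.tips()}
    missing = [t for t in present if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    if not present:
        return 0.0
    counts = np.ones(len(present))
    return float(_skbio_faith_pd(counts, present, tree))


def alpha_diversity_table(
    table: TaxonTable,
    tree: skbio.TreeNode | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-sample alpha-diversity records at the table's finest level.

    Chao1 is only defined for counts-mode tables and is NaN otherwise;
    faith_pd is NaN when no tree is supplied.
    """
    records = []
    is_counts = table.mode == "counts"
    for sample in table.sample_ids:
        row = table.data.loc[sample].to_numpy(dtype=float)
        total = row.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total abundance")
        props = row / total
        present = [t for t, v in zip(table.taxon_ids, row) if v > 0]
        records.append(
            {
                "sample_id": sample,
                "richness": richness(row),
                "shannon": shannon(props, base=base),
                "chao1": chao1(row) if is_counts else np.nan,
                "inverse_simpson": inverse_simpson(props),
                "faith_pd": faith_pd(present, tree) if tree is not None else np.nan,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")
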