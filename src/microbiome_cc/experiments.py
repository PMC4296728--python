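"""Replicated simulation experiments: calibration, power, and FDR control.

These drive the self-validation of the pipeline on the built-in simulator:
type-I error of the clustering permutation test under the exchangeable null,
its power plus affected-taxon recovery under a multiplicative concentration
shift, and empirical false-discovery control of the BH step.  Problem sizes
default to desk-scale study conditions (tens to a couple of hundred samples,
one hundred taxa at 10,000 reads).
"""

from __future__ import annotations

import numpy as np

from .beta import divergence_matrix
from .inference import bh_fdr, group_clustering_permutation_test, taxon_wald_tests
from .simulate import SimulationConfig, simulate_dataset
from .table import collapse_to_level, to_relative

__all__ = [
    "null_rejection_rate",
    "effect_power_and_recovery",
    "fdr_empirical_control",
]


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 1)


def null_rejection_rate(
    n_reps: int = 500,
    n_cases: int = 20,
    n_controls: int = 20,
    n_taxa: int = 100,
    B: int = 199,
    alpha: float = 0.05,
    level: str = "genus",
    seed: int = 0,
) -> float:
    """Type-I error of the clustering permutation test under the null.

    Each replicate simulates an exchangeable dataset (effect_size = 1),
    computes the level-collapsed J-S divergence matrix, runs the one-sided
    permutation test, and counts rejections at ``alpha``.
    """
    seeds = _rep_seeds(seed, n_reps)
    rejections = 0
    for s in seeds:
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, n_taxa=n_taxa,
            effect_size=1.0, seed=int(s),
        )
        ds = simulate_dataset(cfg)
        rel = collapse_to_level(to_relative(ds.table), level)
        D = divergence_matrix(rel, level)
        case = (ds.metadata["CSECTION"] == "yes").to_numpy()
        res = group_clustering_permutation_test(D, case, B=B, seed=int(s) + 1)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def effect_power_and_recovery(
    n_reps: int = 100,
    n_cases: int = 100,
    n_controls: int = 100,
    n_taxa: int = 100,
    effect_size: float = 4.0,
    effect_taxa_fraction: float = 0.1,
    B: int = 199,
    alpha: float = 0.05,
    level: str = "genus",
    rank_quantile: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Power of the permutation test and Wald-rank recovery of affected taxa.

    Per replicate: simulate a shifted dataset, (a) run the clustering
    permutation test on the level-collapsed J-S matrix, (b) run the
    covariate-adjusted taxon Wald screen at the finest level and check the
    smallest ``rank_quantile`` fraction of p-values against the ground-truth
    affected set.  Returns the rejection rate, the fraction of replicates
    whose bottom-quantile p-values are all affected taxa, and the mean
    difference between median p-value ranks of unaffected and affected taxa
    (positive = affected taxa rank earlier).
    """
    seeds = _rep_seeds(seed, n_reps)
    n_bottom = max(1, int(rank_quantile * n_taxa))
    rejections = 0
    rank_successes = 0
    rank_gaps = []
    for s in seeds:
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, n_taxa=n_taxa,
            effect_size=effect_size, effect_taxa_fraction=effect_taxa_fraction,
            seed=int(s),
        )
        ds = simulate_dataset(cfg)
        rel = to_relative(ds.table)
        D = divergence_matrix(collapse_to_level(rel, level), level)
        case = (ds.metadata["CSECTION"] == "yes")
        res = group_clustering_permutation_test(D, case.to_numpy(), B=B, seed=int(s) + 1)
        rejections += res.p_value <= alpha

        assoc = taxon_wald_tests(rel, ds.metadata, case)
        ranks = assoc["wald_p"].rank(method="average")
        affected = set(ds.affected_taxa)
        bottom = set(assoc["wald_p"].nsmallest(n_bottom).index)
        rank_successes += bottom <= affected
        med_aff = ranks[ranks.index.isin(affected)].median()
        med_unaff = ranks[~ranks.index.isin(affected)].median()
        rank_gaps.append(float(med_unaff - med_aff))
    return {
        "rejection_rate": rejections / n_reps,
        "rank_success_rate": rank_successes / n_reps,
        "mean_median_rank_gap": float(np.mean(rank_gaps)),
    }


def fdr_empirical_control(
    n_reps: int = 500,
    m: int = 100,
    alpha: float = 0.05,
    n_alternatives: int = 0,
    alt_scale: float = 1e-4,
    seed: int = 0,
) -> float:
    """Empirical false-discovery rate of the BH step on uniform null p-values.

    Each replicate draws ``m`` p-values (``n_alternatives`` of them from a
    small-valued alternative), adjusts with :func:`bh_fdr`, rejects at
    ``alpha`` and records the false-discovery proportion; the mean FDP over
    replicates estimates the FDR, which BH bounds by alpha * m0 / m.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_reps):
        p = rng.uniform(size=m)
        if n_alternatives:
            p[:n_alternatives] = rng.uniform(size=n_alternatives) * alt_scale
        q = bh_fdr(p)
        rejected = q <= alpha
        n_rej = int(rejected.sum())
        false_rej = int(rejected[n_alternatives:].sum())
        fdps.append(false_rej / n_rej if n_rej else 0.0)
    return float(np.mean(fdps))
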