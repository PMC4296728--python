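"""Statistical testing for case-control microbiome composition.

The primary beta-diversity test asks whether the case group is unusually
tightly clustered on a pairwise J-S divergence matrix: the observed statistic
is the mean pairwise divergence among case samples, and the null is built by
permuting case labels over all samples.  The one-sided p-value (cases more
mutually similar than random label sets) carries the +1 correction
p = (1 + #{null <= observed}) / (1 + B).

Taxon-wise screening regresses case status on each taxon's relative
abundance plus age, sex and race via logistic regression (IRLS, so perfectly
separated cells surface as huge standard errors rather than hard failures,
matching standard glm output), reports the Wald p-value for the abundance
coefficient, and adjusts across taxa with Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .beta import ClusterAssignment, DivergenceMatrix
from .table import TaxonTable

__all__ = [
    "PermutationResult",
    "group_clustering_permutation_test",
    "cluster_case_test",
    "CovariateAssociation",
    "covariate_logistic",
    "TaxonAssociation",
    "taxon_wald_tests",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# permutation test for case-group clustering


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    level: str = ""
    two_sided: bool = False
    exhaustive: bool = False


def _clustering_statistic(D: DivergenceMatrix, case_idx: np.ndarray, statistic: str) -> float:
    within = D.submatrix_mean(case_idx)
    if statistic == "within":
        return within
    if statistic == "within_minus_between":
        n = D.n
        control_idx = np.setdiff1d(np.arange(n), case_idx)
        between = float(D.values[np.ix_(case_idx, control_idx)].mean())
        return within - between
    raise ValueError(f"unknown statistic {statistic!r}")


def group_clustering_permutation_test(
    D: DivergenceMatrix,
    case_labels,
    B: int = 10_000,
    seed: int | None = None,
    statistic: str = "within",
    two_sided: bool = False,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation test for tighter-than-random clustering of the case group.

    Parameters
    ----------
    D : DivergenceMatrix
    case_labels : boolean array-like aligned with ``D.sample_ids``
    B : number of label permutations (ignored when ``exhaustive``)
    statistic : ``within`` (mean pairwise JSD among cases, the default) or
        ``within_minus_between``
    two_sided : report min(2p, 1) where p is the smaller of the two groups'
        one-sided "tighter clustering" p-values; invariant to which group is
        labelled the case group
    exhaustive : enumerate every case-set of the observed size instead of
        sampling; the p-value is then the exact proportion of arrangements
        at least as extreme (the identity arrangement included).
    """
    labels = np.asarray(case_labels, dtype=bool)
    if labels.shape != (D.n,):
        raise ValueError("case_labels must align with the divergence matrix samples")
    n_cases = int(labels.sum())
    n_controls = D.n - n_cases
    if n_cases < 2 or n_controls < 2:
        raise ValueError(f"need >= 2 cases and >= 2 controls, got {n_cases}/{n_controls}")

    case_idx = np.where(labels)[0]
    control_idx = np.where(~labels)[0]
    observed = _clustering_statistic(D, case_idx, statistic)
    observed_ctrl = _clustering_statistic(D, control_idx, statistic)

    if exhaustive:
        arrangements = list(itertools.combinations(range(D.n), n_cases))
        if len(arrangements) > 500_000:
            raise ValueError("too many arrangements to enumerate; use Monte Carlo")
        all_idx = frozenset(range(D.n))
        null = np.array(
            [_clustering_statistic(D, np.array(idx), statistic) for idx in arrangements]
        )
        null_ctrl = np.array(
            [
                _clustering_statistic(D, np.array(sorted(all_idx - set(idx))), statistic)
                for idx in arrangements
            ]
        )
        p_lower = float((null <= observed + 1e-12).mean())
        p_ctrl = float((null_ctrl <= observed_ctrl + 1e-12).mean())
        B_eff = len(arrangements)
    else:
        if B < 99:
            raise ValueError("B must be at least 99")
        rng = np.random.default_rng(seed)
        null = np.empty(B)
        null_ctrl = np.empty(B)
        idx = np.arange(D.n)
        for b in range(B):
            perm = rng.permutation(idx)
            null[b] = _clustering_statistic(D, perm[:n_cases], statistic)
            null_ctrl[b] = _clustering_statistic(D, perm[n_cases:], statistic)
        p_lower = (1 + int((null <= observed + 1e-12).sum())) / (1 + B)
        p_ctrl = (1 + int((null_ctrl <= observed_ctrl + 1e-12).sum())) / (1 + B)
        B_eff = B

    # two-sided: either group unusually tightly clustered (swap-invariant
    # Bonferroni combination of the two one-sided tests)
    p = min(2 * min(p_lower, p_ctrl), 1.0) if two_sided else p_lower
    return PermutationResult(
        statistic=statistic,
        observed=observed,
        n_permutations=B_eff,
        p_value=float(p),
        seed=seed,
        two_sided=two_sided,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# cluster x phenotype contingency test


def cluster_case_test(clusters: ClusterAssignment | pd.Series, case_labels: pd.Series):
    """Pearson chi-square test of independence on the K x 2 cluster-by-case
    table (df = K - 1, no continuity correction).

    Returns ``(chi2, df, p, table)`` where ``table`` has one row per cluster
    and columns ``case``/``control``.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    case = pd.Series(case_labels)
    common = labels.index.intersection(case.index)
    if len(common) < len(labels):
        missing = labels.index.difference(case.index).tolist()
        raise ValueError(f"clustered samples without case label: {missing[:10]}")
    tab = pd.crosstab(labels.loc[common], case.loc[common].astype(bool))
    tab = tab.reindex(columns=[True, False], fill_value=0)
    tab.columns = ["case", "control"]
    if len(tab) < 2:
        raise ValueError("need at least 2 clusters for a contingency test")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), tab


# ---------------------------------------------------------------------------
# logistic regressions


@dataclass
class CovariateAssociation:
    variable: str
    level: str  # "" for continuous predictors
    estimate: float
    std_error: float
    z_value: float
    p_value: float
    converged: bool = True
    flagged: bool = False  # separation / non-convergence suspicion


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Binomial GLM via IRLS; mirrors R glm (huge SEs under separation)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    return res


#: Table-1-style covariate battery: (canonical metadata column, kind, reference level)
DEFAULT_COVARIATES: list[tuple[str, str, str | None]] = [
    ("AGE", "continuous", None),
    ("BMI", "continuous", None),
    ("SEX", "binary", "female"),
    ("GLUTEN", "binary", "no"),
    ("LACTOSE", "binary", "no"),
    ("ASTHMA", "binary", "no"),
    ("RACE", "categorical", "Caucasian"),
    ("REGION", "categorical", "California"),
    ("ANTIBIOTIC_SELECT", "categorical", "None in past year"),
    ("WEIGHT_CHANGE", "categorical", "Remained stable"),
    ("DIET_TYPE", "categorical", "Omnivore"),
    ("ALCOHOL_FREQUENCY", "categorical", "Never"),
    ("SMOKING_FREQUENCY", "categorical", "Never"),
]


def covariate_logistic(
    metadata: pd.DataFrame,
    case: pd.Series,
    variables: list[tuple[str, str, str | None]] | None = None,
) -> list[CovariateAssociation]:
    """One unadjusted logistic regression of case status per variable.

    Continuous variables contribute a single slope; categorical variables are
    dummy-expanded against the given reference level.  Constant predictors
    are flagged, not fatal.  ``case`` is boolean, aligned with ``metadata``.
    """
    variables = DEFAULT_COVARIATES if variables is None else variables
    y = case.loc[metadata.index].astype(float).to_numpy()
    out: list[CovariateAssociation] = []
    for name, kind, ref in variables:
        if name not in metadata.columns:
            continue
        col = metadata[name]
        if kind == "continuous":
            x = pd.to_numeric(col, errors="coerce")
            mask = x.notna().to_numpy()
            if x[mask].nunique() < 2:
                out.append(CovariateAssociation(name, "", np.nan, np.nan, np.nan, np.nan, flagged=True))
                continue
            X = sm.add_constant(pd.DataFrame({name: x[mask].astype(float)}))
            res = _fit_logit(y[mask], X)
            est, se = float(res.params[name]), float(res.bse[name])
            out.append(
                CovariateAssociation(
                    name, "", est, se, est / se, float(res.pvalues[name]),
                    converged=bool(res.converged), flagged=not res.converged or se > 50,
                )
            )
        else:
            vals = col.astype(str)
            levels = sorted(vals.unique())
            if kind == "binary":
                # treat the non-reference level(s) as "yes"-style indicators
                levels = [l for l in levels if l != ref]
            else:
                if ref in levels:
                    levels = [l for l in levels if l != ref]
            if not levels:
                out.append(CovariateAssociation(name, "", np.nan, np.nan, np.nan, np.nan, flagged=True))
                continue
            dummies = pd.DataFrame({l: (vals == l).astype(float) for l in levels}, index=metadata.index)
            # drop empty and constant indicator columns (they carry no contrast)
            keep = [c for c in dummies.columns if 0 < dummies[c].sum() < len(dummies)]
            dummies = dummies[keep]
            if dummies.shape[1] == 0:
                out.append(CovariateAssociation(name, "", np.nan, np.nan, np.nan, np.nan, flagged=True))
                continue
            X = sm.add_constant(dummies)
            res = _fit_logit(y, X)
            for l in dummies.columns:
                est, se = float(res.params[l]), float(res.bse[l])
                out.append(
                    CovariateAssociation(
                        name, l, est, se, est / se, float(res.pvalues[l]),
                        converged=bool(res.converged), flagged=not res.converged or se > 50,
                    )
                )
    return out


@dataclass
class TaxonAssociation:
    lineage: str
    estimate: float
    wald_p: float
    q_value: float
    control_mean: float
    case_mean: float
    difference: float
    converged: bool = True


def _covariate_design(metadata: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    parts: dict[str, pd.Series] = {}
    for name in covariates:
        if name not in metadata.columns:
            raise ValueError(f"metadata lacks covariate column {name!r}")
        col = metadata[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            parts[name] = numeric.astype(float)
        else:
            vals = col.astype(str)
            # drop the most frequent level as reference
            ref = vals.value_counts().idxmax()
            for l in sorted(vals.unique()):
                if l == ref:
                    continue
                parts[f"{name}[{l}]"] = (vals == l).astype(float)
    return pd.DataFrame(parts, index=metadata.index)


def taxon_wald_tests(
    table: TaxonTable,
    metadata: pd.DataFrame,
    case: pd.Series,
    covariates: tuple[str, ...] = ("AGE", "SEX", "RACE"),
    transform: str | None = None,
) -> pd.DataFrame:
    """Per-taxon covariate-adjusted logistic screen.

    For each taxon, fits ``case ~ abundance + covariates`` by logistic
    regression and reports the Wald p-value of the abundance coefficient,
    the per-group mean relative abundances and their difference, plus the
    Benjamini-Hochberg q-value across all tested taxa.  Zero-variance taxa
    are skipped (NaN row).  ``transform='arcsin_sqrt'`` applies the
    variance-stabilising arcsine-square-root to abundances first.
    """
    if table.mode not in ("relative", "pooled"):
        raise ValueError("taxon_wald_tests requires relative abundances")
    ids = metadata.index
    tab = table.data.loc[ids]
    y = case.loc[ids].astype(float).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    Z = _covariate_design(metadata, covariates) if covariates else pd.DataFrame(index=ids)

    case_mask = y == 1
    rows = []
    for taxon in tab.columns:
        x = tab[taxon].to_numpy(dtype=float)
        control_mean = float(x[~case_mask].mean())
        case_mean = float(x[case_mask].mean())
        if np.ptp(x) == 0:
            rows.append(
                dict(lineage=taxon, estimate=np.nan, wald_p=np.nan,
                     control_mean=control_mean, case_mean=case_mean,
                     difference=case_mean - control_mean, converged=False)
            )
            continue
        xr = np.arcsin(np.sqrt(np.clip(x, 0, 1))) if transform == "arcsin_sqrt" else x
        X = pd.DataFrame({"abundance": xr}, index=ids).join(Z)
        X = sm.add_constant(X)
        res = _fit_logit(y, X)
        rows.append(
            dict(lineage=taxon, estimate=float(res.params["abundance"]),
                 wald_p=float(res.pvalues["abundance"]),
                 control_mean=control_mean, case_mean=case_mean,
                 difference=case_mean - control_mean,
                 converged=bool(res.converged))
        )
    out = pd.DataFrame(rows).set_index("lineage")
    tested = out["wald_p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if tested.any():
        q.loc[tested] = bh_fdr(out.loc[tested, "wald_p"].to_numpy())
    out.insert(2, "q_value", q)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
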