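"""Permutation tests, contingency tests, logistic screens, and FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from microbiome_cc import (
    DivergenceMatrix,
    SimulationConfig,
    TaxonTable,
    bh_fdr,
    cluster_case_test,
    covariate_logistic,
    divergence_matrix,
    group_clustering_permutation_test,
    simulate_dataset,
    taxon_wald_tests,
    to_relative,
)


def _random_divergence_matrix(n, seed):
    rng = np.random.default_rng(seed)
    comps = rng.dirichlet(np.full(12, 0.5), size=n)
    t = TaxonTable(
        pd.DataFrame(comps, index=[f"S{i}" for i in range(n)],
                     columns=[f"T{j}" for j in range(12)]),
        mode="relative",
    )
    return divergence_matrix(t)


class TestPermutationTest:
    def test_duplicated_case_composition_minimal_p(self):
        """Cases that are literal copies give statistic 0 and the smallest
        attainable p-value 1/(1+B)."""
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.full(8, 0.5), size=17)
        comps = np.vstack([np.tile(base[0], (4, 1)), base[1:]])
        n = comps.shape[0]
        t = TaxonTable(
            pd.DataFrame(comps, index=[f"S{i}" for i in range(n)],
                         columns=[f"T{j}" for j in range(8)]),
            mode="relative",
        )
        D = divergence_matrix(t)
        labels = np.zeros(n, bool)
        labels[:4] = True
        res = group_clustering_permutation_test(D, labels, B=199, seed=2)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 200)

    def test_exhaustive_enumeration_oracle(self):
        """n=6, 3 cases: Monte-Carlo p converges to the exact enumeration p
        over all 20 case-set arrangements."""
        D = _random_divergence_matrix(6, seed=3)
        labels = np.array([True, True, True, False, False, False])
        exact = group_clustering_permutation_test(D, labels, exhaustive=True)
        # independent enumeration with plain itertools
        obs = D.submatrix_mean(np.where(labels)[0])
        stats = [
            D.submatrix_mean(np.array(idx))
            for idx in itertools.combinations(range(6), 3)
        ]
        assert exact.n_permutations == 20
        assert exact.p_value == pytest.approx(
            sum(s <= obs + 1e-12 for s in stats) / 20
        )
        mc = group_clustering_permutation_test(D, labels, B=20_000, seed=4)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_two_sided_invariant_to_label_swap(self):
        D = _random_divergence_matrix(12, seed=5)
        labels = np.zeros(12, bool)
        labels[:5] = True
        a = group_clustering_permutation_test(D, labels, exhaustive=True, two_sided=True)
        b = group_clustering_permutation_test(D, ~labels, exhaustive=True, two_sided=True)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_degenerate_labels_rejected(self):
        D = _random_divergence_matrix(6, seed=6)
        with pytest.raises(ValueError, match="cases"):
            group_clustering_permutation_test(D, np.ones(6, bool), B=99)
        with pytest.raises(ValueError, match="cases"):
            group_clustering_permutation_test(D, np.zeros(6, bool), B=99)

    def test_null_p_values_super_uniform(self):
        """Under label-exchangeable data the permutation p-value is (super-)
        uniform: one-sided KS should not find excess small p-values."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(100):
            D = _random_divergence_matrix(14, seed=rng.integers(2**31))
            labels = np.zeros(14, bool)
            labels[rng.choice(14, 5, replace=False)] = True
            res = group_clustering_permutation_test(D, labels, B=99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        # empirical CDF must not exceed uniform by much at any small threshold
        for thr in (0.05, 0.1, 0.25):
            assert np.mean(np.array(pvals) <= thr) <= thr + 0.08

    def test_within_minus_between_statistic(self):
        D = _random_divergence_matrix(10, seed=8)
        labels = np.zeros(10, bool)
        labels[:4] = True
        res = group_clustering_permutation_test(
            D, labels, statistic="within_minus_between", exhaustive=True
        )
        idx_c, idx_n = np.where(labels)[0], np.where(~labels)[0]
        expected = D.submatrix_mean(idx_c) - D.values[np.ix_(idx_c, idx_n)].mean()
        assert res.observed == pytest.approx(expected)


class TestClusterCaseTest:
    def test_printed_fourcluster_table(self):
        """10/114, 0/30, 28/209, 54/689 cases per cluster gives p near 0.03."""
        labels = pd.Series(
            ["A"] * 114 + ["B"] * 30 + ["C"] * 209 + ["D"] * 689,
            index=[f"S{i}" for i in range(1042)],
        )
        case = pd.Series(False, index=labels.index)
        case.iloc[:10] = True
        case.iloc[144:172] = True          # 28 of cluster C
        case.iloc[353:407] = True          # 54 of cluster D
        chi2, dof, p, tab = cluster_case_test(labels, case)
        assert dof == 3
        assert tab["case"].tolist() == [10, 0, 28, 54]
        assert round(p, 2) == 0.03

    def test_equal_proportions_p_one(self):
        labels = pd.Series(["A"] * 20 + ["B"] * 40, index=range(60))
        case = pd.Series([True] * 5 + [False] * 15 + [True] * 10 + [False] * 30,
                         index=range(60))
        chi2, dof, p, _ = cluster_case_test(labels, case)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_2x2_consistent_with_fisher_ordering(self):
        """Chi-square p orders tables the same way as exact enumeration."""
        rng = np.random.default_rng(9)
        pairs = []
        for _ in range(10):
            n1, n2 = 30, 30
            k1 = int(rng.integers(1, 15))
            k2 = int(rng.integers(1, 15))
            labels = pd.Series(["A"] * n1 + ["B"] * n2, index=range(n1 + n2))
            case = pd.Series([True] * k1 + [False] * (n1 - k1)
                             + [True] * k2 + [False] * (n2 - k2), index=range(n1 + n2))
            _, _, p_chi, tab = cluster_case_test(labels, case)
            p_fisher = scipy.stats.fisher_exact(tab.to_numpy())[1]
            pairs.append((p_chi, p_fisher))
        order_chi = np.argsort([a for a, _ in pairs])
        order_fis = np.argsort([b for _, b in pairs])
        assert scipy.stats.spearmanr([a for a, _ in pairs], [b for _, b in pairs]).statistic > 0.9

    def test_label_permutation_invariance(self):
        labels = pd.Series(["A"] * 25 + ["B"] * 25 + ["C"] * 25, index=range(75))
        rng = np.random.default_rng(10)
        case = pd.Series(rng.random(75) < 0.3, index=range(75))
        chi_a, _, p_a, _ = cluster_case_test(labels, case)
        remap = labels.map({"A": "C", "B": "A", "C": "B"})
        chi_b, _, p_b, _ = cluster_case_test(remap, case)
        assert chi_a == pytest.approx(chi_b)
        assert p_a == pytest.approx(p_b)

    def test_single_cluster_rejected(self):
        labels = pd.Series(["A"] * 10, index=range(10))
        case = pd.Series([True] * 3 + [False] * 7, index=range(10))
        with pytest.raises(ValueError, match="2 clusters"):
            cluster_case_test(labels, case)


class TestCovariateLogistic:
    def test_age_effect_recovered(self):
        """A known log-odds/year slope is recovered within 3 SE at n=2000."""
        rng = np.random.default_rng(11)
        n, beta = 2000, 0.05
        age = rng.normal(46, 16, n)
        logits = beta * (age - 46) - 1.0
        case = pd.Series(rng.random(n) < 1 / (1 + np.exp(-logits)), index=range(n))
        md = pd.DataFrame({"AGE": age}, index=range(n))
        rows = covariate_logistic(md, case, [("AGE", "continuous", None)])
        (row,) = rows
        assert abs(row.estimate - beta) < 3 * row.std_error
        assert row.z_value == pytest.approx(row.estimate / row.std_error)

    def test_null_predictor_nominal_coverage(self):
        """|z| < 1.96 in >= 93% of replicates for an unrelated predictor."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 150
            x = rng.normal(size=n)
            case = pd.Series(rng.random(n) < 0.3, index=range(n))
            md = pd.DataFrame({"X": x}, index=range(n))
            (row,) = covariate_logistic(md, case, [("X", "continuous", None)])
            hits += abs(row.z_value) < 1.96
        assert hits / reps >= 0.93

    def test_binary_predictor_equals_log_odds_ratio(self):
        """Saturated-model identity: the coefficient is the table's log OR."""
        md = pd.DataFrame({"GLUTEN": ["yes"] * 30 + ["no"] * 70}, index=range(100))
        case = pd.Series([True] * 12 + [False] * 18 + [True] * 14 + [False] * 56,
                         index=range(100))
        rows = covariate_logistic(md, case, [("GLUTEN", "binary", "no")])
        (row,) = rows
        expected = math.log((12 / 18) / (14 / 56))
        assert row.estimate == pytest.approx(expected, abs=1e-6)

    def test_constant_predictor_flagged(self):
        md = pd.DataFrame({"SMOKE": ["no"] * 40}, index=range(40))
        case = pd.Series([True] * 10 + [False] * 30, index=range(40))
        rows = covariate_logistic(md, case, [("SMOKE", "categorical", "no")])
        (row,) = rows
        assert row.flagged and np.isnan(row.estimate)

    def test_separated_level_flagged_with_huge_se(self):
        """An empty cell yields the glm-style enormous SE, flagged not fatal."""
        md = pd.DataFrame(
            {"RACE": ["Caucasian"] * 90 + ["Other"] * 10}, index=range(100)
        )
        case = pd.Series([True] * 20 + [False] * 80, index=range(100))  # no Other cases
        rows = covariate_logistic(md, case, [("RACE", "categorical", "Caucasian")])
        (row,) = rows
        assert row.flagged
        assert row.std_error > 50


class TestTaxonWaldTests:
    def test_output_row_shape(self, null_dataset):
        rel = to_relative(null_dataset.table)
        case = null_dataset.metadata["CSECTION"] == "yes"
        out = taxon_wald_tests(rel, null_dataset.metadata, case)
        assert list(out.columns) == [
            "estimate", "wald_p", "q_value", "control_mean", "case_mean",
            "difference", "converged",
        ]
        assert (out["q_value"].dropna() >= out["wald_p"].dropna() - 1e-12).all()
        assert out["control_mean"].between(0, 1).all()
        assert out["case_mean"].between(0, 1).all()
        np.testing.assert_allclose(
            out["difference"], out["case_mean"] - out["control_mean"], atol=1e-12
        )

    def test_null_taxon_p_uniform(self):
        """A taxon unrelated to case status yields uniform Wald p-values."""
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            n = 150
            x = rng.dirichlet([2.0, 5.0], size=n)[:, 0]
            md = pd.DataFrame(
                {"AGE": rng.normal(46, 16, n), "SEX": rng.choice(["male", "female"], n)},
                index=[f"S{i}" for i in range(n)],
            )
            case = pd.Series(rng.random(n) < 0.3, index=md.index)
            t = TaxonTable(
                pd.DataFrame({"p__A": x, "p__B": 1 - x}, index=md.index),
                mode="relative",
            )
            out = taxon_wald_tests(t, md, case, covariates=("AGE", "SEX"))
            pvals.append(out.loc["p__A", "wald_p"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_taxon_among_smallest_p(self):
        ds = simulate_dataset(
            SimulationConfig(n_cases=100, n_controls=100, n_taxa=40,
                             effect_size=4.0, effect_taxa_fraction=0.05, seed=14)
        )
        rel = to_relative(ds.table)
        case = ds.metadata["CSECTION"] == "yes"
        out = taxon_wald_tests(rel, ds.metadata, case)
        cutoff = out["wald_p"].quantile(0.1)
        assert all(out.loc[t, "wald_p"] <= cutoff for t in ds.affected_taxa)

    def test_zero_variance_taxon_skipped(self, null_dataset):
        rel = to_relative(null_dataset.table)
        data = rel.data.copy()
        data["constant"] = 0.0
        t = TaxonTable(data, mode="pooled")
        case = null_dataset.metadata["CSECTION"] == "yes"
        out = taxon_wald_tests(t, null_dataset.metadata, case)
        assert np.isnan(out.loc["constant", "wald_p"])

    def test_no_covariates_matches_single_predictor_fit(self, null_dataset):
        """With covariates disabled the fit reduces to the simple model."""
        import statsmodels.api as sm

        rel = to_relative(null_dataset.table)
        case = null_dataset.metadata["CSECTION"] == "yes"
        out = taxon_wald_tests(rel, null_dataset.metadata, case, covariates=())
        taxon = out.index[0]
        x = rel.data[taxon].to_numpy()
        X = sm.add_constant(x)
        res = sm.GLM(case.astype(float).to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert out.loc[taxon, "wald_p"] == pytest.approx(res.pvalues[1], rel=1e-6)


class TestBHFDR:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr([0.5, 1.5])
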