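"""Eigengene-trait correlations, group contrasts, and differential stats."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata, ttest_ind

import coexnet as cx


@pytest.fixture(scope="module")
def trait_setup(small_data, small_eigengenes):
    specs = (cx.TraitSpec("driven", 0, 1.0, 1.0),
             cx.TraitSpec("weak", 1, 0.5, 1.0),
             cx.TraitSpec("noise", None, 0.0, 1.0))
    traits = cx.generate_traits(small_data.factors_a, specs, seed=2)
    report = cx.me_trait_correlations(small_eigengenes.eigengenes, traits)
    return traits, report


class TestMETraitCorrelations:
    def test_me_equal_to_trait_gives_r_one(self, small_eigengenes):
        me = small_eigengenes.eigengenes
        traits = pd.DataFrame({"self": me.iloc[0]}, index=me.columns)
        rep = cx.me_trait_correlations(me, traits)
        assert rep.r.loc[me.index[0], "self"] == pytest.approx(1.0)
        assert rep.p.loc[me.index[0], "self"] < 1e-20

    def test_p_matches_independent_oracle(self, small_eigengenes,
                                          trait_setup):
        """Student asymptotic p agrees with scipy.stats.pearsonr per cell."""
        traits, report = trait_setup
        me = small_eigengenes.eigengenes
        for m in me.index:
            for t in ("driven", "noise"):
                r, p = pearsonr(me.loc[m], traits[t])
                assert report.r.loc[m, t] == pytest.approx(r, abs=1e-12)
                assert report.p.loc[m, t] == pytest.approx(p, abs=1e-10)

    def test_q_values_are_bh_monotone(self, trait_setup):
        _, report = trait_setup
        assert (report.q.to_numpy() >= report.p.to_numpy() - 1e-12).all()

    def test_constant_trait_rejected(self, small_eigengenes):
        me = small_eigengenes.eigengenes
        traits = pd.DataFrame({"flat": 1.0}, index=me.columns)
        with pytest.raises(ValueError, match="constant"):
            cx.me_trait_correlations(me, traits)

    def test_driven_trait_correlates_with_its_module(self, trait_setup):
        _, report = trait_setup
        assert abs(report.r.loc["m1", "driven"]) > \
            report.r["driven"].drop("m1").abs().max()


class TestTraitSummary:
    def test_equal_absolute_correlations_collapse_ci(self):
        r = pd.DataFrame({"t": [0.4, -0.4, 0.4]}, index=["a", "b", "c"])
        rep = cx.TraitCorrelationReport(r=r, p=r * 0, q=r * 0, n=r * 0 + 10)
        out = cx.trait_summary(rep, n_boot=200, seed=0)
        assert out.loc["t", "mean_abs_r"] == pytest.approx(0.4)
        assert out.loc["t", "ci_low"] == pytest.approx(0.4)
        assert out.loc["t", "ci_high"] == pytest.approx(0.4)

    def test_bootstrap_deterministic_given_seed(self, trait_setup):
        _, report = trait_setup
        a = cx.trait_summary(report, n_boot=500, seed=5)
        b = cx.trait_summary(report, n_boot=500, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_driven_trait_exceeds_noise_trait(self, trait_setup):
        _, report = trait_setup
        out = cx.trait_summary(report, n_boot=1000, seed=1)
        assert out.loc["driven", "mean_abs_r"] > out.loc["noise",
                                                         "mean_abs_r"]

    def test_single_module_warns(self):
        r = pd.DataFrame({"t": [0.4]}, index=["a"])
        rep = cx.TraitCorrelationReport(r=r, p=r * 0, q=r * 0, n=r * 0 + 10)
        with pytest.warns(UserWarning):
            out = cx.trait_summary(rep, seed=0)
        assert np.isnan(out.loc["t", "ci_low"])


class TestGroupComparison:
    def test_exact_p_for_fully_separated_groups(self):
        """4 vs 4 fully separated values: exact permutation p = 2/70."""
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0],
                           index=list("abcdefgh"))
        groups = pd.Series(["lo"] * 4 + ["hi"] * 4, index=values.index)
        h, p = cx.group_trait_comparison(values, groups, exact=True)
        assert p == pytest.approx(2 / 70)
        # independent enumeration oracle over all C(8,4) splits
        vals = values.to_numpy()
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(combo)] = True
            r = rankdata(vals)
            n = 8
            h_perm = (12 / (n * (n + 1))
                      * (r[mask].sum() ** 2 / 4 + r[~mask].sum() ** 2 / 4)
                      - 3 * (n + 1))
            total += 1
            if h_perm >= h - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_identical_distributions_give_h_zero(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=values.index)
        h, p = cx.group_trait_comparison(values, groups)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_identical_values_rejected(self):
        values = pd.Series([2.0] * 6, index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=values.index)
        with pytest.raises(ValueError):
            cx.group_trait_comparison(values, groups)

    def test_null_labels_calibrated(self):
        """Random group labels give p < 0.05 about 5% of the time."""
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            values = pd.Series(rng.standard_normal(12),
                               index=[f"m{i}" for i in range(12)])
            groups = pd.Series(rng.permutation(["a"] * 6 + ["b"] * 6),
                               index=values.index)
            _, p = cx.group_trait_comparison(values, groups)
            hits += p < 0.05
        assert hits / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestRankRegression:
    def test_monotone_decreasing_gives_rho_minus_one(self):
        ranks = np.arange(1, 9, dtype=float)
        r = 1.0 - 0.1 * ranks
        out = cx.rank_vs_correlation_regression(ranks, r)
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_matches_rank_oracle_on_fixture(self):
        rng = np.random.default_rng(11)
        ranks = np.arange(1, 11, dtype=float)
        r = rng.standard_normal(10)
        out = cx.rank_vs_correlation_regression(ranks, r)
        expected = np.corrcoef(rankdata(ranks), rankdata(r))[0, 1]
        assert out["spearman_rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            cx.rank_vs_correlation_regression(np.ones(5), np.arange(5.0))


class TestDifferential:
    def test_identical_groups_give_t_zero(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((5, 8)),
                         index=[f"g{i}" for i in range(5)])
        kin = pd.Series(rng.random(5), index=X.index)
        rep = cx.diff_expression_vs_connectivity(X, X.copy(), kin, kin)
        np.testing.assert_allclose(rep.table["t"], 0.0, atol=1e-12)

    def test_zero_correlation_gives_fisher_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        # r is tiny but not exactly 0 for arbitrary vectors; force r = 0
        r, p = cx.fisher_z_corr_test(x, y)
        if r == 0:
            assert p == 1.0
        assert 0 <= p <= 1

    def test_matches_welch_oracle(self, small_data):
        """Per-gene t and p agree with scipy's Welch test."""
        genes = small_data.expr_a.index[:100]
        A = small_data.expr_a.loc[genes]
        B = small_data.expr_b.loc[genes]
        kin = pd.Series(1.0, index=genes)
        rep = cx.diff_expression_vs_connectivity(A, B, kin, kin)
        t_or, p_or = ttest_ind(A.to_numpy(), B.to_numpy(), axis=1,
                               equal_var=False)
        np.testing.assert_allclose(rep.table["t"], t_or, atol=1e-10)
        np.testing.assert_allclose(rep.table["p"], p_or, atol=1e-10)

    def test_pooled_variant_matches_oracle(self, small_data):
        genes = small_data.expr_a.index[:50]
        A = small_data.expr_a.loc[genes]
        B = small_data.expr_b.loc[genes]
        kin = pd.Series(1.0, index=genes)
        rep = cx.diff_expression_vs_connectivity(A, B, kin, kin,
                                                 equal_var=True)
        t_or, p_or = ttest_ind(A.to_numpy(), B.to_numpy(), axis=1,
                               equal_var=True)
        np.testing.assert_allclose(rep.table["t"], t_or, atol=1e-10)
        np.testing.assert_allclose(rep.table["p"], p_or, atol=1e-10)

    def test_zero_variance_both_regions_rejected(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"])
        kin = pd.Series([0.0], index=["flat"])
        with pytest.raises(ValueError, match="flat"):
            cx.diff_expression_vs_connectivity(X, X.copy(), kin, kin)
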