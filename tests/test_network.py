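"""Adjacency, TOM, scale-free threshold selection and the tree cut."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

import coexnet as cx
from conftest import random_adjacency


def _expr_with_cor(r_kind: str) -> pd.DataFrame:
    """Tiny matrices with exact pairwise correlations 1, -1 or 0."""
    x = np.array([1.0, -1.0, 1.0, -1.0])
    if r_kind == "plus1":
        y = 2 * x + 3
    elif r_kind == "minus1":
        y = -x
    else:  # exactly orthogonal after centering
        y = np.array([1.0, 1.0, -1.0, -1.0])
    return pd.DataFrame([x, y], index=["a", "b"],
                        columns=[f"s{i}" for i in range(4)])


class TestSignedAdjacency:
    @pytest.mark.parametrize("kind,expected", [
        ("plus1", 1.0),
        ("minus1", 0.0),
        ("zero", 0.5 ** 14),   # = 1/16384
    ])
    def test_exact_values_at_beta_14(self, kind, expected):
        A = cx.signed_adjacency(_expr_with_cor(kind), beta=14)
        assert A.loc["a", "b"] == pytest.approx(expected, abs=1e-15)
        assert A.loc["a", "a"] == 1.0

    def test_zero_variance_gene_identified(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]],
                            index=["ok", "flat"], columns=list("xyz"))
        with pytest.raises(ValueError, match="flat"):
            cx.signed_adjacency(expr, beta=14)

    def test_invalid_beta_and_sample_count(self):
        expr = _expr_with_cor("zero")
        with pytest.raises(ValueError):
            cx.signed_adjacency(expr, beta=0.5)
        with pytest.raises(ValueError):
            cx.signed_adjacency(expr.iloc[:, :2], beta=14)


def tom_loop_oracle(A: np.ndarray) -> np.ndarray:
    """O(n^3) literal implementation of the TOM formula."""
    n = A.shape[0]
    T = np.eye(n)
    k = np.array([sum(A[i, u] for u in range(n) if u != i)
                  for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n)
                       if u != i and u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTOM:
    def test_three_gene_worked_case(self):
        """All off-diagonal a=0.5 -> TO = (0.25+0.5)/(1+1-0.5) = 0.5."""
        A = pd.DataFrame(0.5 * np.ones((3, 3)), index=list("abc"),
                         columns=list("abc"))
        np.fill_diagonal(A.values, 1.0)
        T = cx.tom_similarity(A)
        assert T.loc["a", "b"] == pytest.approx(0.5, abs=1e-15)

    def test_isolated_gene_has_zero_overlap(self):
        A = random_adjacency(6, seed=0)
        A.iloc[0, 1:] = 0.0
        A.iloc[1:, 0] = 0.0
        T = cx.tom_similarity(A)
        assert (T.iloc[0, 1:] == 0).all()

    @pytest.mark.parametrize("n,seed", [(20, 0), (35, 1), (50, 2)])
    def test_matches_cubic_loop_oracle(self, n, seed):
        A = random_adjacency(n, seed=seed)
        T = cx.tom_similarity(A)
        expected = tom_loop_oracle(A.to_numpy())
        np.testing.assert_allclose(T.to_numpy(), expected, atol=1e-12)

    def test_equals_adjacency_when_no_shared_neighbors(self):
        """Perfect-matching graph: every pair shares no neighbors."""
        A = np.eye(6)
        for i, j, w in [(0, 1, 0.7), (2, 3, 0.4), (4, 5, 0.9)]:
            A[i, j] = A[j, i] = w
        A = pd.DataFrame(A, index=list("abcdef"), columns=list("abcdef"))
        T = cx.tom_similarity(A)
        np.testing.assert_allclose(T.to_numpy(), A.to_numpy(), atol=1e-12)

    def test_symmetry_bounds_and_label_invariance(self):
        A = random_adjacency(30, seed=3)
        T = cx.tom_similarity(A)
        M = T.to_numpy()
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert M.min() >= 0 and M.max() <= 1
        perm = np.random.default_rng(4).permutation(30)
        order = A.index[perm]
        T2 = cx.tom_similarity(A.loc[order, order])
        np.testing.assert_allclose(T2.to_numpy(),
                                   T.loc[order, order].to_numpy(),
                                   atol=1e-12)

    def test_rejects_invalid_input(self):
        bad = random_adjacency(5, seed=5)
        bad.iloc[0, 1] = 2.0
        with pytest.raises(ValueError):
            cx.tom_similarity(bad)
        asym = random_adjacency(5, seed=6)
        asym.iloc[0, 1] = 0.1
        asym.iloc[1, 0] = 0.9
        with pytest.raises(ValueError):
            cx.tom_similarity(asym)


class TestSoftThreshold:
    @staticmethod
    def hub_data() -> pd.DataFrame:
        """One module with widely spread loadings: hub-heavy connectivity."""
        design = cx.PlantedDesign(
            n_genes=300, n_samples_region_a=30, module_sizes=(80,),
            preserved=(True,), loading_range=(0.3, 0.95), noise_sd=0.5,
            trait_specs=(), seed=8)
        return cx.generate_two_region_dataset(design).expr_a

    def test_vacuous_cut_returns_smallest_candidate(self):
        st = cx.pick_soft_threshold(self.hub_data(),
                                    candidate_betas=(3, 4, 6), r2_cut=0.0)
        assert st.beta == 3

    def test_matches_independent_brute_force_scan(self, small_data):
        """Selection agrees with an exhaustive per-beta re-fit in the test."""
        expr = small_data.expr_a.iloc[:200]
        betas = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14)
        st = cx.pick_soft_threshold(expr, candidate_betas=betas, r2_cut=0.8)

        def signed_r2(k, n_bins=10):
            logk = np.log10(k[k > 0])
            edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
            idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
            xs, ys = [], []
            for b in range(n_bins):
                m = idx == b
                if m.any():
                    xs.append(np.log10(np.mean(10 ** logk[m])))
                    ys.append(np.log10(m.sum() / len(logk)))
            fit = linregress(xs, ys)
            return fit.rvalue ** 2 * -np.sign(fit.slope)

        C = np.clip(np.corrcoef(expr.to_numpy()), -1, 1)
        base = (1 + C) / 2
        np.fill_diagonal(base, 0.0)
        fits = {b: signed_r2((base ** b).sum(1)) for b in betas}
        passing = [b for b in betas if fits[b] >= 0.8]
        expected = passing[0] if passing else max(fits, key=fits.get)
        assert st.beta == expected
        for b in betas:
            assert st.fit_table.loc[b, "signed_r2"] == pytest.approx(
                fits[b], abs=1e-10)

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError):
            cx.scale_free_fit(np.ones(50))


class TestClusterAndCut:
    def test_recovers_two_planted_blocks(self):
        design = cx.PlantedDesign(
            n_genes=100, module_sizes=(50, 50), preserved=(True, True),
            trait_specs=(), seed=2)
        data = cx.generate_two_region_dataset(design)
        net = cx.build_network(data.expr_a, beta=14)
        det = cx.cluster_and_cut(net.dissimilarity)
        labels = det.labels
        assert set(labels.unique()) == {"turquoise", "blue"}
        # labels assigned by decreasing size
        sizes = labels.value_counts()
        assert sizes["turquoise"] >= sizes["blue"]
        # each planted module maps to a single detected label
        for m in ("m1", "m2"):
            members = data.truth_a.index[data.truth_a == m]
            assert labels.loc[members].nunique() == 1

    def test_too_few_genes_all_grey(self):
        D = pd.DataFrame(np.zeros((5, 5)), index=list("abcde"),
                         columns=list("abcde"))
        with pytest.warns(UserWarning):
            det = cx.cluster_and_cut(D, min_module_size=10)
        assert (det.labels == "grey").all()

    def test_no_module_below_min_size(self):
        rng = np.random.default_rng(8)
        for seed in range(3):
            D = 1 - random_adjacency(60, seed=seed)
            np.fill_diagonal(D.values, 0.0)
            det = cx.cluster_and_cut(D, min_module_size=10)
            sizes = det.labels.value_counts()
            for label, size in sizes.items():
                if label != "grey":
                    assert size >= 10
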