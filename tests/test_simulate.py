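"""The planted generator must honor its factor-model closed forms."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coexnet as cx


def test_planted_module_matches_factor_model_closed_form():
    """Mean within-module correlation converges to b^2/(b^2+s^2).

    All pairs share one factor realization, so the error of the pair-
    averaged correlation is driven by the factor sample moments; n=2000
    samples puts it safely inside the 0.02 tolerance.
    """
    b, s = 0.8, 0.5
    design = cx.PlantedDesign(
        n_genes=60, n_samples_region_a=2000, n_samples_region_b=10,
        module_sizes=(30,), preserved=(True,), loading_range=(b, b),
        noise_sd=s, trait_specs=(), seed=7,
    )
    data = cx.generate_two_region_dataset(design)
    members = data.truth_a.index[data.truth_a == "m1"]
    C = np.corrcoef(data.expr_a.loc[members].to_numpy())
    iu = np.triu_indices(len(members), k=1)
    expected = b * b / (b * b + s * s)
    assert abs(C[iu].mean() - expected) < 0.02


def test_background_genes_are_uncorrelated():
    design = cx.PlantedDesign(
        n_genes=80, n_samples_region_a=500, n_samples_region_b=10,
        module_sizes=(20,), preserved=(True,), trait_specs=(), seed=11,
    )
    data = cx.generate_two_region_dataset(design)
    bg = data.truth_a.index[data.truth_a == "grey"]
    C = np.corrcoef(data.expr_a.loc[bg].to_numpy())
    iu = np.triu_indices(len(bg), k=1)
    assert abs(C[iu].mean()) < 0.01


def test_nonpreserved_modules_dissolve_in_region_b():
    """Region-B truth marks non-preserved members grey, and they decorrelate."""
    design = cx.PlantedDesign(
        n_genes=100, n_samples_region_a=10, n_samples_region_b=400,
        module_sizes=(30, 30), preserved=(True, False), trait_specs=(),
        seed=5,
    )
    data = cx.generate_two_region_dataset(design)
    dropped = data.truth_a.index[data.truth_a == "m2"]
    assert (data.truth_b.loc[dropped] == "grey").all()
    kept = data.truth_a.index[data.truth_a == "m1"]
    assert (data.truth_b.loc[kept] == "m1").all()
    C = np.corrcoef(data.expr_b.loc[dropped].to_numpy())
    iu = np.triu_indices(len(dropped), k=1)
    assert abs(C[iu].mean()) < 0.02


def test_generator_is_deterministic(small_design, small_data):
    again = cx.generate_two_region_dataset(small_design)
    pd.testing.assert_frame_equal(small_data.expr_a, again.expr_a)
    pd.testing.assert_frame_equal(small_data.expr_b, again.expr_b)
    pd.testing.assert_series_equal(small_data.truth_a, again.truth_a)
    t1 = cx.generate_traits(small_data.factors_a,
                            (cx.TraitSpec("x", 0, 1.0, 0.5),), seed=9)
    t2 = cx.generate_traits(again.factors_a,
                            (cx.TraitSpec("x", 0, 1.0, 0.5),), seed=9)
    pd.testing.assert_frame_equal(t1, t2)


@pytest.mark.parametrize("kwargs", [
    dict(module_sizes=(3000,), preserved=(True,)),          # exceeds n_genes
    dict(module_sizes=(1, 50), preserved=(True, True)),     # module below 2
    dict(noise_sd=0.0),                                     # non-positive noise
    dict(noise_sd=-1.0),
    dict(loading_range=(0.0, 0.5)),                         # outside (0, 1]
    dict(loading_range=(0.5, 1.2)),
    dict(preserved=(True,)),                                # flag length mismatch
])
def test_invalid_designs_are_rejected(kwargs):
    base = dict(n_genes=2000, trait_specs=())
    with pytest.raises(ValueError):
        cx.PlantedDesign(**{**base, **kwargs})


class TestTraits:
    def test_noiseless_trait_equals_factor(self, small_data):
        tr = cx.generate_traits(small_data.factors_a,
                                (cx.TraitSpec("t", 0, 1.0, 0.0),), seed=0,
                                binary_from=None)
        r = np.corrcoef(tr["t"], small_data.factors_a.iloc[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_effect_trait_is_uncorrelated(self, small_data):
        specs = tuple(cx.TraitSpec(f"t{i}", None, 0.0, 1.0)
                      for i in range(200))
        tr = cx.generate_traits(small_data.factors_a, specs, seed=1,
                                binary_from=None)
        r = [np.corrcoef(tr[c], small_data.factors_a.iloc[:, 0])[0, 1]
             for c in tr.columns]
        assert abs(np.mean(r)) < 0.05

    def test_effect_one_noise_one_recovers_inv_sqrt2(self):
        """1,000 replicate traits: mean |cor| with the factor is ~ 1/sqrt(2).

        Replicates span 100 independent factor realizations (10 traits
        each) so the common-factor fluctuation at n=24 averages out.
        """
        design = cx.PlantedDesign(
            n_genes=200, module_sizes=(2,) * 100, preserved=(True,) * 100,
            trait_specs=(), seed=19)
        data = cx.generate_two_region_dataset(design)
        specs = tuple(cx.TraitSpec(f"t{i}", i % 100, 1.0, 1.0)
                      for i in range(1000))
        tr = cx.generate_traits(data.factors_a, specs, seed=2,
                                binary_from=None)
        rs = [np.corrcoef(tr[f"t{i}"],
                          data.factors_a.iloc[:, i % 100])[0, 1]
              for i in range(1000)]
        assert np.mean(np.abs(rs)) == pytest.approx(1 / np.sqrt(2), abs=0.04)

    def test_traits_standardized_and_binary_coded(self, small_data):
        tr = cx.generate_traits(
            small_data.factors_a,
            (cx.TraitSpec("a", 0, 1.0, 1.0), cx.TraitSpec("b", None, 0, 1.0)),
            seed=3,
        )
        assert tr["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert tr["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        assert set(tr["sang"].unique()) <= {0, 1}

    def test_unknown_module_raises(self, small_data):
        with pytest.raises(KeyError):
            cx.generate_traits(small_data.factors_a,
                               (cx.TraitSpec("t", 99, 1.0, 1.0),))


class TestGeneSets:
    def test_full_overlap_term_lies_in_module(self, small_data):
        gs = cx.generate_gene_sets(small_data.truth_a, "m1", set_size=20,
                                   overlap_fraction=1.0, seed=1)
        term = gs.sets["planted_term"]
        assert all(small_data.truth_a[g] == "m1" for g in term)

    def test_zero_overlap_term_avoids_module(self, small_data):
        gs = cx.generate_gene_sets(small_data.truth_a, "m1", set_size=20,
                                   overlap_fraction=0.0, seed=1)
        assert all(small_data.truth_a[g] != "m1"
                   for g in gs.sets["planted_term"])

    def test_planted_term_is_strongly_enriched(self):
        """0.8 overlap, set 20, module 100 of 2000 -> Fisher p below 1e-10."""
        truth = pd.Series(
            ["m1"] * 100 + ["grey"] * 1900,
            index=[f"g{i}" for i in range(2000)], name="module")
        gs = cx.generate_gene_sets(truth, "m1", set_size=20,
                                   overlap_fraction=0.8, seed=4)
        module = list(truth.index[truth == "m1"])
        res = cx.fisher_enrichment(module, gs.sets["planted_term"],
                                   list(truth.index))
        assert res.count == 16
        assert res.p_value < 1e-10

    def test_oversized_set_rejected(self, small_data):
        with pytest.raises(ValueError):
            cx.generate_gene_sets(small_data.truth_a, "m1",
                                  set_size=10_000)
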