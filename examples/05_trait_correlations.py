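"""Relate module eigengenes to behavioral traits.

Each module is summarized by its eigengene (first principal component);
correlating eigengenes with per-sample traits reveals which modules
track which behaviors. Student asymptotic p-values and BH q-values are
reported per cell; per-trait mean |r| gets a bootstrap CI.
"""

import coexnet as cx

design = cx.PlantedDesign(
    n_genes=400, module_sizes=(60, 50, 40, 40), preserved=(True,) * 4,
    trait_specs=(cx.TraitSpec("pitch_goodness", 0, 1.0, 1.0),
                 cx.TraitSpec("fm", 1, -0.8, 1.0),
                 cx.TraitSpec("age", None, 0.0, 1.0)),
    seed=2)
data = cx.generate_two_region_dataset(design)
traits = cx.generate_traits(data.factors_a, design.trait_specs, seed=3)

es = cx.module_eigengenes(data.expr_a, data.truth_a)
report = cx.me_trait_correlations(es.eigengenes, traits)

print("eigengene-trait correlations (r):")
print(report.r.round(3).to_string())
print("\np-values (Student asymptotic):")
print(report.p.round(4).to_string())

summary = cx.trait_summary(report, n_boot=2000, seed=4)
print("\nper-trait mean |r| with bootstrap 95% CI:")
print(summary.round(3).to_string())
print("\n'pitch_goodness' is planted on module m1 and 'fm' (negatively) "
      "on m2;\ntheir cells show strong r with small p, while 'age' is "
      "noise throughout.")
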