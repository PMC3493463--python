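"""Module preservation statistics between two regions.

Reference-region module memberships are applied to the test region's
data; permutation Z statistics quantify whether each module's density
and connectivity patterns recur there. Zsummary > 10 = strongly
preserved, 2-10 = moderate, < 2 = not preserved.
"""

import coexnet as cx

design = cx.PlantedDesign(
    n_genes=400, module_sizes=(60, 50, 40, 40),
    preserved=(True, True, False, False), trait_specs=(), seed=3)
data = cx.generate_two_region_dataset(design)

report = cx.preservation_statistics(
    data.expr_a, data.expr_b, data.truth_a, beta=14, n_perm=200, seed=1)
print("preservation summary (m1/m2 preserved, m3/m4 dissolved by design):")
cols = ["size", "z_density", "z_connectivity", "z_summary",
        "median_rank_summary"]
print(report.summary[cols].round(2).to_string())

ranking = cx.preservation_ranking(report)
print("\ncomposite ranking (1 = most preserved):")
print(ranking.round(2).to_string())

quality = cx.quality_statistics(data.expr_a, data.truth_a, beta=14,
                                n_perm=200, seed=2)
print("\nmodule quality (same machinery, test = reference data):")
print(quality.summary[["size", "z_summary"]].round(2).to_string())
print("\nPreserved planted modules score Zsummary >> 10 and rank first; "
      "dissolved\nmodules score < 2. All planted modules are high-quality "
      "in their own region.")
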