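# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `coexnet`.

## Network model

Expression is a genes × samples matrix per tissue; all correlations are
Pearson (the Student asymptotic p-values used downstream presuppose it).
The adjacency is *signed*: `a_ij = ((1 + cor)/2)^β`, so anti-correlated
genes get near-zero weight instead of being conflated with positively
correlated ones. β defaults to 14; `pick_soft_threshold` implements the
scale-free topology criterion (bin log10 connectivity into 10 bins, regress
log-frequency on log-mean-connectivity, signed fit index R² × −sign(slope),
smallest power reaching 0.80 wins) for data where β should be chosen from
the data. Missing values are disallowed — microarray matrices are complete
after preprocessing, and the contracts stay simple. Zero-variance genes are
rejected by name.

Topological overlap uses the standard formula with unit diagonal; the
implementation is the matrix-product form and is tested element-wise
against a literal O(n³) loop. When two genes share no neighbors, TO reduces
to the adjacency (verified on matching graphs).

## Module detection

Average-linkage hierarchical clustering of `1 − TO` with a deterministic
fixed-height branch cut: the tree is cut at
`min_height + cut_height_frac × (max_height − min_height)`, clusters below
`min_module_size` (default 10) become grey background, and surviving
modules are labeled by decreasing size from a fixed color sequence
("turquoise" is always the largest module).

`cut_height_frac` defaults to **0.85**. The top of an average-linkage TOM
dendrogram is dominated by two kinds of merges that should *not* define
modules: background genes attaching to module branches, and module-module
joins. Cutting very close to the top (e.g. at 0.99 of the range) merges
distinct modules and sweeps most background genes into them; a calibration
scan on the default planted design showed that 0.85 recovers every planted
module with 95.5–99.9% of planted genes retained and survivor ARI 0.94–0.96
across seeds, while higher cuts degrade both. The parameter is exposed for
data with different dendrogram geometry. A hybrid-style post-step
(`attach_background_by_kme`) can attach grey genes to the module of their
highest kME above a threshold; it is off by default so membership comes
purely from the tree.

No eigengene-based module merging is performed.

## Density filter

Module density is the mean TO over unordered within-module pairs. The null
compares each module against `n_perm` pseudo-modules of the same size drawn
uniformly (without replacement within a draw) from the *current* network's
genes; `p` counts strict exceedances, so the smallest nonzero p is
1/n_perm and a module tied with every pseudo-module gets p = 0 (pseudo-
module index sets are gathered in sorted order so that ties are exact in
floating point). A conservative `(count+1)/(n_perm+1)` variant is available
via `smoothed=True`. Default n_perm is 10,000 with α = 0.01.

The filter then removes genes of failing modules plus all grey genes,
rebuilds the network at the same β, and iterates. The gene set is
non-increasing and each non-terminal iteration removes at least one gene,
so termination is guaranteed; a fully dissolving input returns an empty
network with a warning.

## Preservation and quality

Reference module memberships are applied unchanged to the test data. Per
module, three density statistics (mean within-module test adjacency; mean
of sign(cor_ref)·cor_test over pairs; mean of sign(kME_ref)·kME_test over
members, kME taken against the member set's own first principal component
in each dataset) and three connectivity statistics (cross-dataset
correlations of member kIN, of member kME, and of the within-module
adjacency pattern) are standardized against a permutation null in which
the full label vector is reshuffled over the network's genes (module sizes
preserved; default 200 permutations). Zdensity and Zconnectivity are the
medians of their groups and Zsummary their mean; statistics with zero
permutation variance (tolerance 1e-8) are excluded from the medians with a
warning. Median ranks are computed from the observed statistics (rank 1 =
best, ties averaged); the composite preservation rank is the mean of the
summary median rank and the rank of Zsummary, which is a declared,
deterministic approximation — the field's composite ranking is not
standardized.

Quality statistics run the same machinery with test = reference. All three
cross-dataset connectivity statistics are then identically 1 under every
permutation, so they are excluded and quality Zsummary reduces to the
density component by construction.

Under the synthetic block design the connectivity Z scores are
conservative: permuted pseudo-modules mix genes from several preserved
blocks and therefore inherit strong cross-region connectivity structure,
which can exceed the within-module loading gradient of a single genuine
module. Separation of preserved from dissolved modules is carried by the
density component and is large (> 15 Z units at the default design). On
real tissue, where the network is not a set of near-orthogonal blocks,
the connectivity statistics are more informative.

## Traits

Eigengenes are the first right singular vector of the z-scored (unit
sample variance) module submatrix, sign-oriented so mean member kME ≥ 0,
rescaled to unit variance. Because genes are row-centered, the eigengene
is exactly centered and variance explained equals the mean squared member
kME (asserted to 1e-8 in tests). Gene standardization before the
decomposition is a deliberate choice: it makes eigengenes scale-free and
the kME/variance-explained identity exact.

ME–trait correlations use t = r√(n−2)/√(1−r²) on n−2 df, two-sided, with
BH q-values over the whole module × trait matrix; the display convention
follows raw p < 0.05. The per-trait mean |r| gets a nonparametric
bootstrap CI over modules (percentile, default 2,000 resamples) — the CI
construction is a package choice, as no standard exists for this summary.
Binary traits are correlated point-biserially (plain Pearson on 0/1).
Group contrasts use tie-corrected Kruskal–Wallis with the chi-square
approximation; an `exact=True` mode enumerates group assignments (n ≤ 12)
for small-sample checks. Differential expression between regions uses
Welch's t by default (pooled variant via `equal_var=True`), and the t
statistics are related to kIN differences via Fisher-z correlation tests.

## Enrichment

One-sided Fisher exact (hypergeometric upper tail) against the full
post-preprocessing universe — never the smaller filtered network — with
terms intersected with the universe before testing. BH FDR is computed
within each module across its tested terms (matching per-module term
lists); terms with FDR > 15% or fewer than 3 overlapping genes are
dropped. TS = mean kME of the term's module genes (w.r.t. the module's
own eigengene) × (1 − p), sorted descending with ties broken by smaller p
then term label. Depletion is not reported.

## Synthetic data

Each planted module is a latent factor block: per-sample factor
f ~ N(0,1), member gene `x = μ_g + b·f + ε` with loading b ~ U(0.6, 0.9),
noise ε ~ N(0, 0.5²), and a gene-specific baseline μ_g ~ N(8,1) shared
across regions (so cross-region expression-level comparisons behave like
normalized log-intensities). Background genes are independent N(0,1)
noise around their baseline. Preserved modules keep memberships and
loadings in region B with fresh factors; non-preserved members become
background there. Loadings are drawn uniformly so that kME varies within
a module, which the kME-based statistics need. Traits are
`effect · f + N(0, noise_sd²)`, standardized to zero mean and unit
variance so `cor(trait, f) = effect/√(effect² + noise_sd²)` exactly in
expectation; one binary trait thresholds the first continuous trait at
its median. All generators are pure functions of (design, seed).

The default design — 2,000 genes, 8 modules of 100–250 genes, 4 preserved
and 4 region-specific, 25% background, 24 and 26 samples — is a desk-scale
mirror of a dual-region songbird microarray study (thousands of genes,
~17 modules of 34–937 genes). The generator does **not** emulate probe-
level artifacts, batch effects, heavy-tailed microarray noise, sample
outliers, or correlated background structure; passing tests demonstrate
the statistical machinery is correct and calibrated under the factor
model, not that any particular biological dataset will behave this way.

## Problem sizes used by the test suite and acceptance script

The library defaults stay at study scale (n_perm 10,000 for the density
null, 200 for preservation). The test suite and `scripts/acceptance.py`
run the same algorithms at reduced permutation counts (density 200–2,000,
preservation 40–200) and 400–2,000-gene designs; these sizes were chosen
so every Monte-Carlo check keeps a comfortable error margin. The recovery
experiment runs the full default 2,000-gene design for five seeds.

## Numerical details

- Correlation matrices are clipped to [−1, 1] before powering.
- Equal collapse means tie-break to the lexicographically smallest probe
  id; equal module sizes tie-break by first gene index; TS ties break by
  smaller p then term label — all orderings are deterministic.
- A single master seed fans out to stage seeds by fixed offsets, so runs
  are bit-reproducible end to end and per stage.
- Degenerate inputs (constant traits, zero-variance genes, singleton
  modules, empty universes, all-identical group values) raise ValueError
  with offending identifiers rather than propagating NaN.

## Known limitations

- The preservation statistic battery is a documented six-statistic subset
  of the published preservation literature, not the full set; the
  composite ranking is likewise an approximation.
- Pseudo-modules are sampled from the current iteration's gene set; the
  alternative (the original gene set) is not implemented.
- No block-wise construction: networks above ~20k genes will not fit the
  dense-matrix implementation.
- DAVID-style EASE-adjusted enrichment scores and functional-annotation
  clustering are out of scope; enrichment is plain Fisher on user-supplied
  gene sets.
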