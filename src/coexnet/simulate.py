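"""Two-region synthetic expression data with planted module structure.

The generator emulates a paired-tissue microarray study: two brain
regions share gene identity but only part of the co-expression structure.
Each planted module is a latent-factor block: the module has one latent
factor per sample, drawn standard normal, and a member gene ``g`` is

    x_g = mu_g + b_g * f_m + eps,   eps ~ N(0, noise_sd^2)

with a gene-specific loading ``b_g`` drawn uniformly from
``loading_range``. Background genes are pure noise. Modules flagged
preserved reuse the same memberships and loadings in region B (with
fresh factor realizations); non-preserved modules dissolve into
background noise in region B. Traits are linear functions of selected
region-A module factors plus noise, and gene sets are planted inside a
chosen module so the enrichment stage has ground truth.

Under this model two member genes with loadings ``b_i, b_j`` have
expected correlation ``b_i b_j / sqrt((b_i^2+s^2)(b_j^2+s^2))`` where
``s = noise_sd``; a trait with effect ``a`` and trait noise ``t`` has
expected correlation ``a / sqrt(a^2+t^2)`` with its driving factor.

Everything is a pure function of (design, seed): the same design yields
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .colors import GREY
from .io import GeneSetCollection


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: driven by a module factor, plus noise.

    ``module`` indexes into the planted modules (None for a pure-noise
    trait); ``effect`` is the linear coefficient on the factor and
    ``noise_sd`` the standard deviation of the additive trait noise.
    """

    name: str
    module: int | None
    effect: float
    noise_sd: float


DEFAULT_TRAIT_SPECS: tuple[TraitSpec, ...] = (
    TraitSpec("motifs", 0, 1.0, 1.0),
    TraitSpec("pitch", 1, 0.8, 1.0),
    TraitSpec("pitch_goodness", 4, 1.0, 1.0),
    TraitSpec("wiener_entropy", 5, 0.8, 1.0),
    TraitSpec("fm", 4, -0.8, 1.0),
    TraitSpec("age", None, 0.0, 1.0),
)


@dataclasses.dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted two-region design.

    The default mirrors a desk-scale version of a dual-region songbird
    striato-pallidum study: 2,000 genes, 8 latent-factor modules of
    40-250 genes (4 preserved across regions, 4 region-specific), 25%
    background, and 24 / 26 samples in the two regions.
    """

    n_genes: int = 2000
    n_samples_region_a: int = 24
    n_samples_region_b: int = 26
    module_sizes: tuple[int, ...] = (250, 235, 220, 205, 190, 160, 140, 100)
    preserved: tuple[bool, ...] = (True, True, True, True,
                                   False, False, False, False)
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 0.5
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAIT_SPECS
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module needs at least 2 genes")
        if len(self.preserved) != len(self.module_sizes):
            raise ValueError("preserved flags must match module_sizes")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for spec in self.trait_specs:
            if spec.module is not None and not (
                0 <= spec.module < len(self.module_sizes)
            ):
                raise ValueError(f"trait {spec.name!r}: unknown module "
                                 f"{spec.module}")
            if spec.noise_sd < 0:
                raise ValueError(f"trait {spec.name!r}: negative noise_sd")

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    @property
    def background_fraction(self) -> float:
        return self.n_background / self.n_genes

    @property
    def module_names(self) -> tuple[str, ...]:
        return tuple(f"m{i + 1}" for i in range(len(self.module_sizes)))


@dataclasses.dataclass
class TwoRegionDataset:
    """Output of :func:`generate_two_region_dataset`."""

    expr_a: pd.DataFrame          # genes x samples, region A (reference)
    expr_b: pd.DataFrame          # genes x samples, region B (test)
    truth_a: pd.Series            # gene -> planted module label ('grey' bg)
    truth_b: pd.Series            # same in region B (non-preserved -> grey)
    factors_a: pd.DataFrame       # samples x modules latent factors, region A
    factors_b: pd.DataFrame       # samples x modules, region B
    loadings: pd.Series           # gene -> loading (NaN for background)
    design: PlantedDesign


def generate_two_region_dataset(design: PlantedDesign) -> TwoRegionDataset:
    """Draw one two-region dataset from the planted design.

    Gene identity is shared across regions. Preserved modules keep
    memberships and loadings in region B; non-preserved module members
    become independent noise there. A gene-specific baseline level
    (shared between regions, emulating log-intensity) is added so that
    cross-region expression-level comparisons are meaningful.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    names = [f"g{i:05d}" for i in range(1, n + 1)]
    samples_a = [f"A{j:02d}" for j in range(1, design.n_samples_region_a + 1)]
    samples_b = [f"B{j:02d}" for j in range(1, design.n_samples_region_b + 1)]

    sizes = design.module_sizes
    bounds = np.cumsum((0,) + sizes)
    members = [list(range(bounds[k], bounds[k + 1])) for k in range(len(sizes))]

    truth_a = np.full(n, GREY, dtype=object)
    loadings = np.full(n, np.nan)
    lo, hi = design.loading_range
    for k, idx in enumerate(members):
        truth_a[idx] = design.module_names[k]
        loadings[idx] = rng.uniform(lo, hi, size=len(idx))

    baseline = rng.normal(8.0, 1.0, size=n)

    def _region(n_samples: int, active: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
        factors = rng.standard_normal((n_samples, len(sizes)))
        X = rng.normal(0.0, 1.0, size=(n, n_samples))  # background noise, sd 1
        for k, idx in enumerate(members):
            if not active[k]:
                continue  # members stay as the independent noise drawn above
            b = loadings[idx][:, None]
            eps = rng.normal(0.0, design.noise_sd, size=(len(idx), n_samples))
            X[idx] = b * factors[:, k][None, :] + eps
        return X + baseline[:, None], factors

    Xa, Fa = _region(design.n_samples_region_a, [True] * len(sizes))
    Xb, Fb = _region(design.n_samples_region_b, design.preserved)

    truth_b = truth_a.copy()
    for k, idx in enumerate(members):
        if not design.preserved[k]:
            truth_b[idx] = GREY

    return TwoRegionDataset(
        expr_a=pd.DataFrame(Xa, index=names, columns=samples_a),
        expr_b=pd.DataFrame(Xb, index=names, columns=samples_b),
        truth_a=pd.Series(truth_a, index=names, name="module"),
        truth_b=pd.Series(truth_b, index=names, name="module"),
        factors_a=pd.DataFrame(Fa, index=samples_a,
                               columns=list(design.module_names)),
        factors_b=pd.DataFrame(Fb, index=samples_b,
                               columns=list(design.module_names)),
        loadings=pd.Series(loadings, index=names, name="loading"),
        design=design,
    )


def generate_traits(
    factors: pd.DataFrame,
    trait_specs: Sequence[TraitSpec],
    seed: int = 0,
    binary_from: str | None = "first",
) -> pd.DataFrame:
    """Build a samples x traits table from module latent factors.

    Each continuous trait is ``effect * factor + N(0, noise_sd^2)``,
    standardized to zero mean and unit variance so the closed-form
    trait-factor correlation ``effect / sqrt(effect^2 + noise_sd^2)``
    is exact in expectation. One binary 0/1 trait (``sang``) is derived
    by thresholding the first continuous trait at its median, emulating
    a sang / did-not-sing grouping; pass ``binary_from=None`` to skip it.
    """
    rng = np.random.default_rng(seed)
    n = len(factors)
    out: dict[str, np.ndarray] = {}
    for spec in trait_specs:
        if spec.module is None:
            base = np.zeros(n)
        else:
            key = spec.module
            if isinstance(key, int):
                if not (0 <= key < factors.shape[1]):
                    raise KeyError(f"unknown module index {key}")
                f = factors.iloc[:, key].to_numpy()
            else:
                if key not in factors.columns:
                    raise KeyError(f"unknown module id {key!r}")
                f = factors[key].to_numpy()
            base = spec.effect * f
        t = base + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 \
            else base.astype(float)
        sd = t.std()
        if sd > 0:
            t = (t - t.mean()) / sd
        out[spec.name] = t
    traits = pd.DataFrame(out, index=factors.index)
    if binary_from is not None and len(trait_specs) > 0:
        src = traits.columns[0] if binary_from == "first" else binary_from
        traits["sang"] = (traits[src] > traits[src].median()).astype(int)
    return traits


def generate_gene_sets(
    truth: pd.Series,
    enriched_module: str,
    set_size: int = 20,
    overlap_fraction: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Emit one term planted inside a module plus a random control term.

    The planted term draws ``round(overlap_fraction * set_size)`` genes
    from *enriched_module* and fills the remainder from background
    (grey) genes; the control term is drawn uniformly from the whole
    universe. Sampling is without replacement.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    universe = list(truth.index)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe "
                         f"{len(universe)}")
    rng = np.random.default_rng(seed)
    module_genes = list(truth.index[truth == enriched_module])
    if not module_genes:
        raise ValueError(f"unknown module {enriched_module!r}")
    grey_genes = list(truth.index[truth == GREY])

    n_in = round(overlap_fraction * set_size)
    n_in = min(n_in, len(module_genes))
    n_out = set_size - n_in
    pool_out = grey_genes if grey_genes else \
        [g for g in universe if truth[g] != enriched_module]
    if n_out > len(pool_out):
        raise ValueError("not enough background genes for the term")
    term = list(rng.choice(module_genes, size=n_in, replace=False)) + \
        list(rng.choice(pool_out, size=n_out, replace=False))
    control = list(rng.choice(universe, size=set_size, replace=False))
    return GeneSetCollection(
        sets={"planted_term": term, "random_control": control},
        descriptions={
            "planted_term": f"{n_in}/{set_size} genes from {enriched_module}",
            "random_control": "uniform random draw from the universe",
        },
    )
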