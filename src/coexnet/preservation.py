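"""Permutation-based module preservation and quality statistics.

Reference module memberships are applied, unchanged, to a test dataset
and the question is whether the module's internal structure recurs
there. Six statistics are computed per module, three about density and
three about connectivity:

density
    ``mean_adjacency``  — mean within-module signed adjacency in test;
    ``mean_signed_cor`` — mean of sign(cor_ref) * cor_test over pairs;
    ``mean_signed_kme`` — mean of sign(kME_ref) * kME_test over members,
    with kME taken against the module's first principal component in
    each dataset.

connectivity
    ``cor_kin``        — correlation of member kIN between datasets;
    ``cor_kme``        — correlation of member kME between datasets;
    ``cor_adjacency``  — correlation of the within-module adjacency
    pattern (upper triangle) between datasets.

Each statistic is standardized against a permutation null in which
module labels are randomly reassigned to the test network's genes
(module sizes preserved): Z = (obs - mean_perm) / sd_perm. Zdensity and
Zconnectivity are the medians of their groups and Zsummary is their
mean. Zsummary > 10 indicates strong preservation, 2-10 moderate, < 2
none. Median ranks (rank 1 = best observed statistic among modules)
give a complementary, composition-independent ordering.

Running the machinery with the test dataset equal to the reference
yields module *quality* statistics: how dense and distinct the modules
are in their own data. In that case the three cross-dataset
connectivity statistics are identically 1 for both observed and
permuted modules (zero permutation variance), so they are excluded and
quality Zsummary reduces to the density component.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .colors import GREY

DENSITY_STATS = ("mean_adjacency", "mean_signed_cor", "mean_signed_kme")
CONNECTIVITY_STATS = ("cor_kin", "cor_kme", "cor_adjacency")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (X - mean) / sd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _first_pc_kme(Z: np.ndarray, n_samples: int) -> np.ndarray:
    """kME of each row against the set's own first principal component.

    Rows of Z are z-scored (norm sqrt(n-1)), so the correlation of row g
    with the first right singular vector is U[g,0]*s0/sqrt(n-1). Sign is
    oriented so the mean kME is non-negative.
    """
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    kme = U[:, 0] * s[0] / np.sqrt(n_samples - 1)
    if kme.sum() < 0:
        kme = -kme
    return kme


def _module_statistics(
    Zr: np.ndarray, Zt: np.ndarray, idx: np.ndarray, beta: float
) -> np.ndarray:
    """The six preservation statistics for one gene index set."""
    nr, nt = Zr.shape[1], Zt.shape[1]
    Sr, St = Zr[idx], Zt[idx]
    Cr = np.clip(Sr @ Sr.T / (nr - 1), -1.0, 1.0)
    Ct = np.clip(St @ St.T / (nt - 1), -1.0, 1.0)
    Ar = ((1.0 + Cr) / 2.0) ** beta
    At = ((1.0 + Ct) / 2.0) ** beta
    s = len(idx)
    iu = np.triu_indices(s, k=1)

    kme_r = _first_pc_kme(Sr, nr)
    kme_t = _first_pc_kme(St, nt)
    kin_r = Ar.sum(axis=1) - np.diag(Ar)
    kin_t = At.sum(axis=1) - np.diag(At)

    return np.array([
        float(At[iu].mean()),
        float((np.sign(Cr[iu]) * Ct[iu]).mean()),
        float((np.sign(kme_r) * kme_t).mean()),
        _pearson(kin_r, kin_t),
        _pearson(kme_r, kme_t),
        _pearson(Ar[iu], At[iu]),
    ])


def _median_ranks(observed: pd.DataFrame) -> pd.DataFrame:
    """Per-module median rank of observed statistics (rank 1 = best)."""
    ranks = pd.DataFrame(index=observed.index, columns=observed.columns,
                         dtype=float)
    for col in observed.columns:
        vals = observed[col]
        ok = vals.notna()
        if ok.sum() > 0:
            ranks.loc[ok, col] = stats.rankdata(-vals[ok], method="average")
    out = pd.DataFrame(index=observed.index)
    out["median_rank_density"] = ranks[list(DENSITY_STATS)].median(
        axis=1, skipna=True)
    out["median_rank_connectivity"] = ranks[list(CONNECTIVITY_STATS)].median(
        axis=1, skipna=True)
    out["median_rank_summary"] = out[
        ["median_rank_density", "median_rank_connectivity"]
    ].mean(axis=1, skipna=True)
    return out


@dataclasses.dataclass
class PreservationReport:
    """Observed statistics, permutation Zs, and composite summaries."""

    observed: pd.DataFrame   # module x statistic
    z: pd.DataFrame          # module x statistic permutation Z scores
    summary: pd.DataFrame    # Zdensity, Zconnectivity, Zsummary, ranks, size
    n_perm: int
    seed: int | None


def preservation_statistics(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    assignment_ref: pd.Series,
    beta: float,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationReport:
    """Preservation of reference modules in a test dataset.

    Expression matrices must share gene ids (samples may differ). Grey
    genes stay in the permutation pool but are not evaluated as a
    module. Statistics with zero permutation variance get Z = NaN, are
    excluded from the medians, and trigger a warning.
    """
    genes = assignment_ref.index.intersection(expr_ref.index)
    genes = genes.intersection(expr_test.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between reference and test")
    assignment = assignment_ref.loc[genes]
    Zr = _zscore_rows(expr_ref.loc[genes].to_numpy(dtype=float))
    Zt = _zscore_rows(expr_test.loc[genes].to_numpy(dtype=float))
    if np.isnan(Zr).any() or np.isnan(Zt).any():
        raise ValueError("zero-variance genes in reference or test data")

    sizes = assignment[assignment != GREY].value_counts()
    modules = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    if not modules:
        raise ValueError("no non-grey modules to evaluate")
    codes = assignment.to_numpy()

    observed = np.vstack([
        _module_statistics(Zr, Zt, np.nonzero(codes == m)[0], beta)
        for m in modules
    ])

    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, len(modules), len(ALL_STATS)))
    for p in range(n_perm):
        shuffled = rng.permutation(codes)
        for mi, m in enumerate(modules):
            idx = np.nonzero(shuffled == m)[0]
            perm[p, mi] = _module_statistics(Zr, Zt, idx, beta)

    mean_perm = perm.mean(axis=0)
    sd_perm = perm.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - mean_perm) / sd_perm
    degenerate = sd_perm <= 1e-8  # exactly-preserved statistics (e.g. test
    # data identical to reference) have no permutation variance beyond
    # floating noise; their Z is undefined
    if degenerate.any():
        z[degenerate] = np.nan
        warnings.warn(
            "zero permutation variance for some statistics "
            "(identical reference and test data?); excluded from medians"
        )

    obs_df = pd.DataFrame(observed, index=modules, columns=list(ALL_STATS))
    z_df = pd.DataFrame(z, index=modules, columns=list(ALL_STATS))

    summary = pd.DataFrame(index=pd.Index(modules, name="module"))
    summary["size"] = [int(sizes[m]) for m in modules]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        summary["z_density"] = np.nanmedian(
            z_df[list(DENSITY_STATS)].to_numpy(), axis=1)
        summary["z_connectivity"] = np.nanmedian(
            z_df[list(CONNECTIVITY_STATS)].to_numpy(), axis=1)
        summary["z_summary"] = np.nanmean(
            summary[["z_density", "z_connectivity"]].to_numpy(), axis=1)
    summary = summary.join(_median_ranks(obs_df))
    return PreservationReport(observed=obs_df, z=z_df, summary=summary,
                              n_perm=n_perm, seed=seed)


def quality_statistics(
    expr_ref: pd.DataFrame,
    assignment_ref: pd.Series,
    beta: float,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationReport:
    """Module quality: preservation machinery with test = reference data."""
    with warnings.catch_warnings():
        # cross-dataset statistics are degenerate by construction here
        warnings.filterwarnings(
            "ignore", message="zero permutation variance")
        return preservation_statistics(
            expr_ref, expr_ref, assignment_ref, beta,
            n_perm=n_perm, seed=seed,
        )


def preservation_ranking(report: PreservationReport) -> pd.DataFrame:
    """Composite preservation ranking of the evaluated modules.

    The composite rank is the mean of the summary median rank and the
    rank of Zsummary (highest Z = rank 1); modules with identical
    statistics share identical composite ranks. Sorted best first.
    """
    s = report.summary
    z_rank = stats.rankdata(-s["z_summary"].to_numpy(), method="average")
    out = pd.DataFrame({
        "z_summary": s["z_summary"],
        "z_summary_rank": z_rank,
        "median_rank_summary": s["median_rank_summary"],
    }, index=s.index)
    out["composite_rank"] = (out["z_summary_rank"]
                             + out["median_rank_summary"]) / 2.0
    return out.sort_values(["composite_rank", "z_summary"],
                           ascending=[True, False])


def cross_region_scatter_stats(values_ref, values_test) -> dict[str, float]:
    """Rank and linear correlation of paired per-gene statistics.

    Used for expression-level and kIN preservation scatters. Returns
    Spearman rho and Pearson r with their two-sided p-values.
    """
    x = np.asarray(values_ref, dtype=float)
    y = np.asarray(values_test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector")
    rho, rho_p = stats.spearmanr(x, y)
    r, r_p = stats.pearsonr(x, y)
    return {"spearman_rho": float(rho), "spearman_p": float(rho_p),
            "pearson_r": float(r), "pearson_p": float(r_p), "n": int(len(x))}
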