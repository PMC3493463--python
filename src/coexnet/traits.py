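"""Eigengene-trait correlation analysis and differential comparisons.

Module eigengenes summarize each module's expression variability across
samples; correlating them with behavioral traits (amount of singing,
song spectral features, age, a binary sang / did-not-sing grouping)
asks which co-expression modules track which aspects of behavior.
p-values use the Student asymptotic form t = r*sqrt(n-2)/sqrt(1-r^2);
Benjamini-Hochberg q-values are reported alongside. Module-group
contrasts use the Kruskal-Wallis rank test, and per-gene differential
expression between regions (Welch t) is contrasted with differential
intramodular connectivity via Fisher-z correlation tests.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _student_p(r: float, n: int) -> float:
    """Two-sided Student asymptotic p for a Pearson correlation."""
    if n < 3:
        return np.nan
    if 1.0 - r * r <= 0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclasses.dataclass
class TraitCorrelationReport:
    """Module x trait correlation matrix with p- and q-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame  # samples used per cell (after pairwise NaN drop)


def me_trait_correlations(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> TraitCorrelationReport:
    """Pearson correlation of every module eigengene with every trait.

    Eigengenes are modules x samples; traits are samples x traits.
    Samples with a missing trait value are dropped pairwise. q-values
    are Benjamini-Hochberg across the whole module x trait matrix.
    """
    samples = eigengenes.columns.intersection(traits.index)
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples")
    me = eigengenes.loc[:, samples]
    tr = traits.loc[samples]
    for trait in tr.columns:
        vals = tr[trait].dropna()
        if vals.nunique() <= 1:
            raise ValueError(f"constant trait: {trait}")

    modules, trait_names = list(me.index), list(tr.columns)
    r = pd.DataFrame(index=modules, columns=trait_names, dtype=float)
    p = pd.DataFrame(index=modules, columns=trait_names, dtype=float)
    nmat = pd.DataFrame(index=modules, columns=trait_names, dtype=int)
    for trait in trait_names:
        tvals = tr[trait]
        ok = tvals.notna()
        n = int(ok.sum())
        x = tvals[ok].to_numpy(dtype=float)
        for module in modules:
            y = me.loc[module, ok].to_numpy(dtype=float)
            rv = float(np.corrcoef(x, y)[0, 1]) if n >= 3 else np.nan
            rv = float(np.clip(rv, -1.0, 1.0))
            r.loc[module, trait] = rv
            p.loc[module, trait] = _student_p(rv, n)
            nmat.loc[module, trait] = n

    flat = p.to_numpy().ravel()
    ok = ~np.isnan(flat)
    qflat = np.full_like(flat, np.nan)
    if ok.any():
        qflat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    q = pd.DataFrame(qflat.reshape(p.shape), index=p.index, columns=p.columns)
    return TraitCorrelationReport(r=r, p=p, q=q, n=nmat)


def trait_summary(
    report: TraitCorrelationReport,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trait mean |r| over modules with a bootstrap 95% CI.

    Nonparametric bootstrap over modules, percentile method. A single-
    module report yields NaN CIs with a warning.
    """
    absr = report.r.abs()
    m = absr.shape[0]
    if m < 1:
        raise ValueError("empty report")
    out = pd.DataFrame(index=absr.columns,
                       columns=["mean_abs_r", "ci_low", "ci_high"],
                       dtype=float)
    out["mean_abs_r"] = absr.mean(axis=0)
    if m == 1:
        warnings.warn("single module: bootstrap CI undefined")
        return out
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    vals = absr.to_numpy(dtype=float)
    boot = vals[idx].mean(axis=1)            # n_boot x traits
    out["ci_low"] = np.percentile(boot, 2.5, axis=0)
    out["ci_high"] = np.percentile(boot, 97.5, axis=0)
    return out


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    start, h = 0, 0.0
    for g in groups:
        rsum = ranks[start:start + len(g)].sum()
        h += rsum ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else np.nan


def group_trait_comparison(
    values: pd.Series, groups: pd.Series, exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis comparison of module-level values across groups.

    ``values`` holds one number per module (e.g. its ME-trait
    correlation) and ``groups`` the grouping (e.g. meta-module
    membership). The default p-value is the usual tie-corrected
    chi-square approximation; ``exact=True`` enumerates all assignments
    of the observed values to the group sizes (feasible for small
    module counts) and returns the exact permutation p.
    """
    values = values.loc[groups.index]
    arrays = [values[groups == g].to_numpy(dtype=float)
              for g in pd.unique(groups)]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need at least 2 nonempty groups")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        raise ValueError("all values identical")
    h_obs = _kw_statistic(arrays)
    if not exact:
        _, p = stats.kruskal(*arrays)
        return float(h_obs), float(p)

    n = len(flat)
    sizes = [len(a) for a in arrays]
    if n > 12:
        raise ValueError("exact enumeration is limited to n <= 12")
    count = total = 0
    positions = list(range(n))

    def assignments(pos: list[int], remaining_sizes: list[int]):
        if not remaining_sizes:
            yield []
            return
        s = remaining_sizes[0]
        for combo in itertools.combinations(pos, s):
            rest = [q for q in pos if q not in combo]
            for tail in assignments(rest, remaining_sizes[1:]):
                yield [list(combo)] + tail

    for parts in assignments(positions, sizes):
        h = _kw_statistic([flat[p_] for p_ in parts])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return float(h_obs), count / total


def rank_vs_correlation_regression(
    ranks, correlations
) -> dict[str, float]:
    """Spearman association between preservation rank and ME-trait r.

    Also returns the ordinary least-squares line (slope/intercept of r
    on rank) for plotting. Inputs are per-module vectors.
    """
    x = np.asarray(ranks, dtype=float)
    y = np.asarray(correlations, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 modules")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    fit = stats.linregress(x, y)
    return {"spearman_rho": float(rho), "spearman_p": float(p),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "n": int(len(x))}


def fisher_z_corr_test(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided Fisher-z p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    z = math.atanh(r) * math.sqrt(n - 3)
    return r, float(2.0 * stats.norm.sf(abs(z)))


@dataclasses.dataclass
class DifferentialReport:
    """Per-gene differential expression vs differential connectivity."""

    table: pd.DataFrame           # gene: t, p, kin_ref, kin_test, kin_diff
    cor_t_vs_kin_diff: float
    p_t_vs_kin_diff: float
    cor_t_vs_kin_ref: float
    p_t_vs_kin_ref: float


def diff_expression_vs_connectivity(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    kin_ref: pd.Series,
    kin_test: pd.Series,
    equal_var: bool = False,
) -> DifferentialReport:
    """Two-sample t per gene between regions, related to kIN differences.

    Positive t means higher expression in the reference region. Welch's
    t by default (``equal_var=True`` for the pooled variant). The t
    statistics are then correlated with kIN_ref - kIN_test and with
    kIN_ref, with two-sided Fisher-z p-values; genes lacking a kIN in
    either region (grey) are dropped from those correlations.
    """
    genes = expr_ref.index.intersection(expr_test.index)
    if len(genes) == 0:
        raise ValueError("no shared genes")
    A = expr_ref.loc[genes].to_numpy(dtype=float)
    B = expr_test.loc[genes].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per region")
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    both_zero = (va == 0) & (vb == 0)
    if both_zero.any():
        raise ValueError(
            f"zero variance in both regions: "
            f"{genes[both_zero][:10].tolist()}")
    diff = A.mean(axis=1) - B.mean(axis=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = np.full(len(genes), na + nb - 2, dtype=float)
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    kr = kin_ref.reindex(genes).to_numpy(dtype=float)
    kt = kin_test.reindex(genes).to_numpy(dtype=float)
    table = pd.DataFrame({
        "t": t, "p": p, "kin_ref": kr, "kin_test": kt, "kin_diff": kr - kt,
    }, index=genes)
    r1, p1 = fisher_z_corr_test(table["t"], table["kin_diff"])
    r2, p2 = fisher_z_corr_test(table["t"], table["kin_ref"])
    return DifferentialReport(
        table=table,
        cor_t_vs_kin_diff=r1, p_t_vs_kin_diff=p1,
        cor_t_vs_kin_ref=r2, p_t_vs_kin_ref=p2,
    )
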