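"""Probe-to-gene collapsing and the enrichment universe.

Microarrays carry several probes per gene and many probes with no
annotation. The analysis-ready matrix keeps one representative probe per
gene symbol — the probe with the highest mean expression across samples,
which tends to be the most reproducible — and drops unannotated probes
entirely. The full post-collapse gene list is frozen as the reference
universe for all later enrichment tests, even after network filtering
shrinks the analysis set.
"""

from __future__ import annotations

import warnings

import pandas as pd


def drop_unannotated(expr: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove probes whose annotation symbol is empty.

    Every expression row id must be present in the annotation table;
    survivors keep their input order. An all-unannotated matrix returns
    empty with a warning.
    """
    missing = expr.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(f"probes missing from annotation: "
                       f"{missing[:10].tolist()}")
    symbols = annotation.loc[expr.index, "symbol"].astype(str)
    keep = symbols.str.strip() != ""
    if not keep.any():
        warnings.warn("all probes are unannotated; returning empty matrix")
    return expr.loc[keep[keep].index]


def collapse_probes(
    expr: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse annotated probes to one representative row per gene symbol.

    The representative is the probe with the maximal mean across samples;
    ties break to the lexicographically smallest probe id. Returns the
    collapsed matrix (row ids = gene symbols, ordered by first appearance
    of each symbol) and the probe -> gene map actually used.
    """
    missing = expr.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(f"probes missing from annotation: "
                       f"{missing[:10].tolist()}")
    symbols = annotation.loc[expr.index, "symbol"].astype(str)
    if (symbols.str.strip() == "").any():
        raise ValueError("unannotated probes present; run drop_unannotated "
                         "first")

    means = expr.mean(axis=1)
    chosen: dict[str, str] = {}
    order: list[str] = []
    for probe in expr.index:
        sym = symbols[probe]
        if sym not in chosen:
            chosen[sym] = probe
            order.append(sym)
        else:
            best = chosen[sym]
            m_new, m_best = means[probe], means[best]
            if m_new > m_best or (m_new == m_best and probe < best):
                chosen[sym] = probe
    rep_probes = [chosen[sym] for sym in order]
    collapsed = expr.loc[rep_probes].copy()
    collapsed.index = pd.Index(order, name="gene")
    mapping = pd.DataFrame(
        {"probe": rep_probes, "gene": order}
    ).set_index("probe")
    return collapsed, mapping


def define_universe(expr_collapsed: pd.DataFrame) -> list[str]:
    """Freeze the post-collapse gene list as the enrichment universe.

    Called once on the collapsed matrix; the result is reused as the
    reference for every Fisher enrichment test, regardless of how many
    genes survive network density filtering later.
    """
    return list(expr_collapsed.index)


def variance_filter(
    expr: pd.DataFrame,
    min_variance: float | None = None,
    min_level: float | None = None,
) -> pd.DataFrame:
    """Optional pre-filters on per-gene variance and mean level.

    Both default to off (None). These stand in for upstream outlier /
    sub-background probe removal, which is study-specific and not
    modeled here.
    """
    keep = pd.Series(True, index=expr.index)
    if min_variance is not None:
        keep &= expr.var(axis=1) >= min_variance
    if min_level is not None:
        keep &= expr.mean(axis=1) >= min_level
    return expr.loc[keep]
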