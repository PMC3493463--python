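"""Gene-set overrepresentation with term-significance ranking.

Enrichment of user-supplied gene sets (cell-type markers, disease
associations, functional terms) in each module is tested with a
one-sided Fisher exact test against a fixed reference universe — the
full post-preprocessing gene list, not the (smaller) final network.
Terms are filtered by Benjamini-Hochberg FDR (within module) and a
minimum overlap size, and the survivors are ranked by the term
significance (TS) score

    TS = mean kME of the module's term genes * (1 - enrichment p)

which promotes terms that are both strongly enriched and carried by
genes that conform closely to the module's main expression pattern.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .colors import GREY
from .io import GeneSetCollection


class FisherResult(NamedTuple):
    count: int
    odds_ratio: float
    p_value: float


def fisher_enrichment(
    module_genes: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> FisherResult:
    """One-sided over-representation test of a term within a module.

    The term is intersected with the universe before testing; the
    module must already be a subset of the universe. The p-value is the
    hypergeometric upper tail P(X >= overlap).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    module = set(module_genes)
    extra = module - uni
    if extra:
        raise ValueError(f"module genes outside universe: "
                         f"{sorted(extra)[:10]}")
    term = set(term_genes) & uni
    k = len(module & term)
    N, K, n = len(uni), len(term), len(module)
    p = float(hypergeom.sf(k - 1, N, K, n))
    a, b = k, n - k
    c, d = K - k, N - n - K + k
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return FisherResult(count=k, odds_ratio=float(odds), p_value=p)


def enrichment_table(
    assignment: pd.Series,
    gene_sets: GeneSetCollection | Mapping[str, list[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of every term in every non-grey module.

    Returns one row per (module, term) with the overlap count, odds
    ratio, raw p-value and the overlapping gene ids.
    """
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)
    descriptions = (gene_sets.descriptions
                    if isinstance(gene_sets, GeneSetCollection) else {})
    uni = set(universe)
    sizes = assignment[assignment != GREY].value_counts()
    modules = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rows = []
    for module in modules:
        members = set(assignment.index[assignment == module]) & uni
        for term in sorted(sets):
            res = fisher_enrichment(members, sets[term], uni)
            overlap = sorted(members & (set(sets[term]) & uni))
            rows.append({
                "module": module,
                "term": term,
                "description": descriptions.get(term, ""),
                "count": res.count,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "genes": overlap,
            })
    return pd.DataFrame(rows)


def filter_terms(
    results: pd.DataFrame,
    fdr_max: float = 0.15,
    min_genes: int = 3,
) -> pd.DataFrame:
    """FDR and overlap-size filtering of an enrichment table.

    Benjamini-Hochberg FDR is computed within each module across its
    tested terms; rows with FDR > ``fdr_max`` or overlap count below
    ``min_genes`` are dropped.
    """
    if results.empty:
        return results.assign(fdr=pd.Series(dtype=float))
    out = results.copy()
    out["fdr"] = np.nan
    for module, idx in out.groupby("module").groups.items():
        out.loc[idx, "fdr"] = multipletests(
            out.loc[idx, "p_value"].to_numpy(), method="fdr_bh")[1]
    keep = (out["fdr"] <= fdr_max) & (out["count"] >= min_genes)
    return out.loc[keep].reset_index(drop=True)


def term_significance(
    filtered: pd.DataFrame, kme: pd.DataFrame
) -> pd.DataFrame:
    """Rank filtered terms by TS = mean kME of term genes x (1 - p).

    kME is taken with respect to the module's own eigengene (the
    ``kme`` table has genes as rows, modules as columns). Sorted by
    descending TS; ties break by smaller p, then term label.
    """
    if filtered.empty:
        return filtered.assign(avg_kme=pd.Series(dtype=float),
                               ts=pd.Series(dtype=float))
    out = filtered.copy()
    avg, ts = [], []
    for _, row in out.iterrows():
        genes = [g for g in row["genes"] if g in kme.index]
        if not genes or row["module"] not in kme.columns:
            avg.append(np.nan)
            ts.append(np.nan)
            continue
        a = float(kme.loc[genes, row["module"]].mean())
        avg.append(a)
        ts.append(a * (1.0 - row["p_value"]))
    out["avg_kme"] = avg
    out["ts"] = ts
    return out.sort_values(
        ["ts", "p_value", "term"], ascending=[False, True, True]
    ).reset_index(drop=True)


def export_enrichment(results: pd.DataFrame) -> pd.DataFrame:
    """Flatten gene lists for CSV export (Module ... geneSym columns)."""
    out = results.copy()
    out["genes"] = out["genes"].map(";".join)
    rename = {"module": "Module", "description": "Category", "term": "Term",
              "count": "Count", "p_value": "PValue", "fdr": "FDR",
              "avg_kme": "avg.kME", "ts": "TS", "genes": "geneSym"}
    return out.rename(columns={k: v for k, v in rename.items()
                               if k in out.columns})
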