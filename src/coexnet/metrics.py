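"""Module eigengenes, kME, kIN and the eigengene (meta-module) network.

The module eigengene (ME) is the first principal component of the
module's gene-standardized expression, oriented so that the average
correlation between member genes and the ME is non-negative, and scaled
to unit variance. kME is a gene's correlation with an ME (computed
against every module, not just its own, so term-average kME and fuzzy
membership queries are possible); kIN is the sum of a gene's adjacency
weights to its module co-members. Meta-modules are clusters of MEs at
distance 1 - correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .colors import GREY


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene(s) in module")
    return (X - mean) / sd


def _module_order(assignment: pd.Series) -> list[str]:
    sizes = assignment[assignment != GREY].value_counts()
    return sorted(sizes.index, key=lambda m: (-sizes[m], m))


@dataclasses.dataclass
class EigengeneSet:
    """Module x sample eigengene matrix with per-module variance explained."""

    eigengenes: pd.DataFrame      # modules x samples, unit variance rows
    var_explained: pd.Series      # in [0, 1]


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> EigengeneSet:
    """First principal component of each non-grey module.

    Genes are z-scored (unit sample variance) before the decomposition.
    The eigengene is sign-oriented so its mean kME over members is >= 0
    and rescaled to unit variance. Variance explained is the first
    squared singular value over the total, which for standardized genes
    equals the mean squared kME of the members.
    """
    assignment = assignment.loc[expr.index]
    mes: dict[str, np.ndarray] = {}
    varex: dict[str, float] = {}
    for module in _module_order(assignment):
        sub = expr.loc[assignment == module].to_numpy(dtype=float)
        Z = _zscore_rows(sub)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        if U[:, 0].sum() < 0:
            v = -v
        mes[module] = v / v.std(ddof=1)
        varex[module] = float(s[0] ** 2 / (s ** 2).sum())
    return EigengeneSet(
        eigengenes=pd.DataFrame(mes, index=expr.columns).T,
        var_explained=pd.Series(varex, name="var_explained"),
    )


def compute_kme(expr: pd.DataFrame, eigengenes: EigengeneSet | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    me = eigengenes.eigengenes if isinstance(eigengenes, EigengeneSet) else eigengenes
    me = me.loc[:, expr.columns]
    n = expr.shape[1]
    Zg = _zscore_rows(expr.to_numpy(dtype=float))
    Zm = _zscore_rows(me.to_numpy(dtype=float))
    kme = Zg @ Zm.T / (n - 1)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.index, columns=me.index)


def compute_kin(adjacency: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """Intramodular connectivity: sum of adjacency to module co-members.

    Grey background genes get NaN (kIN is undefined outside a module).
    """
    assignment = assignment.loc[adjacency.index]
    kin = pd.Series(np.nan, index=adjacency.index, name="kIN")
    for module in assignment.unique():
        if module == GREY:
            continue
        genes = assignment.index[assignment == module]
        sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
        kin.loc[genes] = sub.sum(axis=1) - np.diag(sub)
    return kin


def connectivity_table(
    expr: pd.DataFrame, adjacency: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Per-gene summary: module label, kIN, and kME against every module."""
    es = module_eigengenes(expr, assignment)
    kme = compute_kme(expr, es)
    kin = compute_kin(adjacency, assignment)
    out = kme.add_prefix("kME.")
    out.insert(0, "module", assignment.loc[expr.index])
    out.insert(1, "kIN", kin)
    return out


@dataclasses.dataclass
class MetaModules:
    """Meta-module partition of the eigengene network."""

    labels: pd.Series             # module -> meta-module id (1-based)
    linkage: np.ndarray
    me_correlation: pd.DataFrame  # symmetric module x module


def meta_modules(
    eigengenes: EigengeneSet | pd.DataFrame,
    k: int | None = 3,
    cut_height: float | None = None,
) -> MetaModules:
    """Cluster module eigengenes at distance 1 - correlation.

    Meta-modules come from a requested branch count ``k`` (default 3) or
    from a fixed dendrogram ``cut_height``; exactly one of the two must
    be given.
    """
    me = eigengenes.eigengenes if isinstance(eigengenes, EigengeneSet) else eigengenes
    m = me.shape[0]
    if m < 2:
        raise ValueError("need at least 2 modules for meta-modules")
    if (k is None) == (cut_height is None):
        raise ValueError("give exactly one of k or cut_height")
    if k is not None and k > m:
        raise ValueError(f"k={k} exceeds module count {m}")
    C = np.clip(np.corrcoef(me.to_numpy(dtype=float)), -1.0, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
    if k is not None:
        flat = fcluster(Z, t=k, criterion="maxclust")
    else:
        flat = fcluster(Z, t=cut_height, criterion="distance")
    return MetaModules(
        labels=pd.Series(flat, index=me.index, name="meta_module"),
        linkage=Z,
        me_correlation=pd.DataFrame(C, index=me.index, columns=me.index),
    )


def attach_background_by_kme(
    expr: pd.DataFrame, assignment: pd.Series, min_kme: float = 0.7
) -> pd.Series:
    """Optional post-step: attach grey genes to their best module by kME.

    A grey gene joins the module with its highest kME when that kME
    reaches ``min_kme``; otherwise it stays grey. Off by default in the
    pipeline — module membership then comes purely from the tree cut.
    """
    out = assignment.copy()
    grey = assignment.index[assignment == GREY]
    if len(grey) == 0 or (assignment != GREY).sum() == 0:
        return out
    es = module_eigengenes(expr, assignment)
    kme = compute_kme(expr.loc[grey], es)
    best = kme.idxmax(axis=1)
    best_val = kme.max(axis=1)
    attach = best_val >= min_kme
    out.loc[grey[attach]] = best[attach]
    return out
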