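"""Signed weighted network construction and module detection.

The network is a signed weighted correlation network: the adjacency
between genes i and j is

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta

so perfectly anti-correlated genes get weight 0 rather than 1, and the
soft-threshold power ``beta`` (chosen by the scale-free topology
criterion) suppresses weak correlations without a hard cutoff.

Genes are clustered on topological overlap (TO), a neighborhood-sharing
similarity that considers each pair in the context of the whole network:

    TO_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with l_ij = sum_u a_iu * a_uj (u != i, j) and k_i the total connectivity
of gene i. Modules are branches of the average-linkage dendrogram of
1 - TO, cut at a fixed height expressed as a fraction of the merge-height
range; branches below the minimum module size become grey background.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .colors import GREY, color_sequence

DEFAULT_BETAS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


def _check_variance(expr: pd.DataFrame) -> None:
    sd = expr.to_numpy(dtype=float).std(axis=1)
    bad = expr.index[sd == 0]
    if len(bad) > 0:
        raise ValueError(f"zero-variance genes: {bad[:10].tolist()}")


def signed_adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed weighted adjacency ``((1 + cor)/2)^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    _check_variance(expr)
    C = np.corrcoef(expr.to_numpy(dtype=float))
    C = np.clip(C, -1.0, 1.0)
    A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.index, columns=expr.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity distribution.

    Bins log10(k), regresses log10(frequency) on log10(mean k per bin)
    and returns ``(R^2 * -sign(slope), slope)``; a high positive value
    indicates an approximately scale-free (power-law, negative slope)
    degree distribution.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    which = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    fit = linregress(xs, ys)
    r2 = fit.rvalue ** 2
    return r2 * -np.sign(fit.slope), float(fit.slope)


@dataclasses.dataclass
class SoftThreshold:
    """Result of scale-free soft-threshold selection."""

    beta: int
    fit_table: pd.DataFrame  # per candidate: signed_r2, slope, mean/median/max k


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas: tuple[int, ...] = DEFAULT_BETAS,
    r2_cut: float = 0.80,
    n_bins: int = 10,
) -> SoftThreshold:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest candidate whose signed fit index reaches
    ``r2_cut``; if none does, the candidate maximizing the index is
    returned with a warning.
    """
    if len(candidate_betas) == 0:
        raise ValueError("no candidate betas")
    if list(candidate_betas) != sorted(candidate_betas):
        raise ValueError("candidate betas must be ascending")
    _check_variance(expr)
    C = np.clip(np.corrcoef(expr.to_numpy(dtype=float)), -1.0, 1.0)
    base = (1.0 + C) / 2.0
    np.fill_diagonal(base, 0.0)  # exclude self from connectivity
    rows = []
    for beta in candidate_betas:
        k = (base ** beta).sum(axis=1)
        signed_r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({
            "beta": beta, "signed_r2": signed_r2, "slope": slope,
            "mean_k": float(k.mean()), "median_k": float(np.median(k)),
            "max_k": float(k.max()),
        })
    table = pd.DataFrame(rows).set_index("beta")
    ok = table.index[table["signed_r2"] >= r2_cut]
    if len(ok) > 0:
        beta = int(ok[0])
    else:
        beta = int(table["signed_r2"].idxmax())
        warnings.warn(
            f"no candidate beta reached signed R^2 >= {r2_cut}; "
            f"using beta={beta} (max signed R^2 "
            f"{table['signed_r2'].max():.3f})"
        )
    return SoftThreshold(beta=beta, fit_table=table)


def _check_adjacency(adjacency: pd.DataFrame) -> np.ndarray:
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    return A


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    Unit diagonal; symmetric; values in [0, 1]. Equals the adjacency
    whenever a gene pair shares no neighbors.
    """
    A = _check_adjacency(adjacency)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0                       # l_ij = sum_{u != i,j} a_iu a_uj
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A0) / denom
    T[denom == 0] = 0.0
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


@dataclasses.dataclass
class NetworkMatrices:
    """Adjacency and TOM of one network, with shared gene order."""

    adjacency: pd.DataFrame
    tom: pd.DataFrame

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.tom


def build_network(expr: pd.DataFrame, beta: float) -> NetworkMatrices:
    A = signed_adjacency(expr, beta)
    return NetworkMatrices(adjacency=A, tom=tom_similarity(A))


@dataclasses.dataclass
class ModuleDetection:
    """Module labels plus the dendrogram they were cut from."""

    labels: pd.Series
    linkage: np.ndarray | None
    cut_height: float | None


def cluster_and_cut(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 10,
    cut_height_frac: float = 0.85,
) -> ModuleDetection:
    """Average-linkage clustering of 1 - TOM with a fixed-height branch cut.

    The tree is cut at ``min_height + cut_height_frac * height_range``;
    resulting clusters smaller than ``min_module_size`` are labeled grey.
    Surviving modules are labeled by decreasing size from the fixed color
    sequence, so the largest module is always "turquoise".
    """
    genes = dissimilarity.index
    n = len(genes)
    if n < min_module_size:
        warnings.warn(f"only {n} genes (< min module size "
                      f"{min_module_size}); all grey")
        return ModuleDetection(
            labels=pd.Series(GREY, index=genes, name="module"),
            linkage=None, cut_height=None,
        )
    D = dissimilarity.to_numpy(dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    if heights.max() == heights.min():
        cut = heights.max() + 1.0  # flat tree: one cluster
    else:
        cut = heights.min() + cut_height_frac * (heights.max() - heights.min())
    flat = fcluster(Z, t=cut, criterion="distance")

    labels = np.full(n, GREY, dtype=object)
    clusters = []
    for c in np.unique(flat):
        idx = np.nonzero(flat == c)[0]
        if len(idx) >= min_module_size:
            clusters.append(idx)
    clusters.sort(key=lambda idx: (-len(idx), idx[0]))
    for color, idx in zip(color_sequence(), clusters):
        labels[idx] = color
    return ModuleDetection(
        labels=pd.Series(labels, index=genes, name="module"),
        linkage=Z, cut_height=float(cut),
    )
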