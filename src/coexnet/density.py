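"""Iterative permutation-based module density filtering.

A module's density is the mean topological overlap across its within-
module gene pairs. Each detected module is compared against pseudo-
modules of the same size drawn uniformly at random from the network's
genes: the p-value is the fraction of pseudo-module densities strictly
greater than the observed density (so a module tied with every pseudo-
module gets p = 0 and the smallest reportable nonzero p is 1/n_perm).

The filter then iterates: genes in modules failing the density test
(p > alpha) and all grey background genes are removed, the network is
rebuilt on the survivors at the same soft threshold, and modules are
re-detected — until every module passes and no grey genes remain. The
gene set is non-increasing, so termination is guaranteed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .colors import GREY
from .network import NetworkMatrices, build_network, cluster_and_cut


def module_density(tom: pd.DataFrame, members) -> float:
    """Mean TO over unordered within-module gene pairs (diagonal excluded)."""
    members = list(members)
    s = len(members)
    if s < 2:
        raise ValueError("module density needs at least 2 members")
    sub = tom.loc[members, members].to_numpy(dtype=float)
    return float((sub.sum() - np.trace(sub)) / (s * (s - 1)))


def density_permutation_test(
    tom: pd.DataFrame,
    assignment: pd.Series,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int | None = None,
    smoothed: bool = False,
) -> pd.DataFrame:
    """Permutation density test of every non-grey module.

    For each module of size s, ``n_perm`` pseudo-modules of size s are
    drawn (without replacement within a draw, independently across
    draws) from the network's current genes; p is the strict-inequality
    exceedance fraction. ``smoothed=True`` uses the conservative
    (count+1)/(n_perm+1) variant instead.

    Returns one row per module: size, density, p_value, passed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    assignment = assignment.loc[tom.index]
    T = tom.to_numpy(dtype=float)
    n = T.shape[0]
    rng = np.random.default_rng(seed)
    sizes = assignment[assignment != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rows = []
    for module in order:
        idx = np.nonzero((assignment == module).to_numpy())[0]
        s = len(idx)
        if s > n:
            raise ValueError(f"module {module} larger than network")
        sub = T[np.ix_(idx, idx)]
        obs = (sub.sum() - np.trace(sub)) / (s * (s - 1))
        # bulk index draws: each row of `draws` is one pseudo-module
        keys = rng.random((n_perm, n))
        draws = np.argpartition(keys, s - 1, axis=1)[:, :s]
        draws.sort(axis=1)  # fixed gather order: ties in density are exact
        pseudo = np.empty(n_perm)
        denom = s * (s - 1)
        for j in range(n_perm):
            psub = T[np.ix_(draws[j], draws[j])]
            pseudo[j] = (psub.sum() - np.trace(psub)) / denom
        exceed = int((pseudo > obs).sum())
        p = (exceed + 1) / (n_perm + 1) if smoothed else exceed / n_perm
        rows.append({"module": module, "size": s, "density": obs,
                     "p_value": p, "passed": p <= alpha})
    result = pd.DataFrame(rows).set_index("module")
    result.attrs["n_perm"] = n_perm
    result.attrs["alpha"] = alpha
    return result


@dataclasses.dataclass
class FilterResult:
    """Outcome of the iterative density filter."""

    assignment: pd.Series              # final gene -> module labels
    network: NetworkMatrices | None    # final adjacency/TOM (None if empty)
    density: pd.DataFrame | None       # final density test table
    log: list[dict]                    # one record per iteration
    converged: bool


def iterative_filter(
    expr: pd.DataFrame,
    beta: float,
    min_module_size: int = 10,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int | None = None,
    cut_height_frac: float = 0.85,
    max_iter: int = 100,
) -> FilterResult:
    """Iterate network build -> module detection -> density cull to a fixed point.

    ``beta`` is chosen once (on the full matrix) and held fixed across
    iterations. Stops when every module passes the density test and no
    grey genes remain; an input that dissolves completely returns an
    empty result with a warning.
    """
    genes = expr.index
    log: list[dict] = []
    for iteration in range(1, max_iter + 1):
        if len(genes) == 0:
            warnings.warn("density filter removed every gene; "
                          "returning empty network")
            return FilterResult(
                assignment=pd.Series(dtype=object, name="module"),
                network=None, density=None, log=log, converged=True,
            )
        sub = expr.loc[genes]
        net = build_network(sub, beta)
        detection = cluster_and_cut(net.dissimilarity,
                                    min_module_size=min_module_size,
                                    cut_height_frac=cut_height_frac)
        labels = detection.labels
        modules = [m for m in labels.unique() if m != GREY]
        it_seed = None if seed is None else seed + 1000 * iteration
        if modules:
            dens = density_permutation_test(
                net.tom, labels, n_perm=n_perm, alpha=alpha, seed=it_seed)
            failing = list(dens.index[~dens["passed"]])
        else:
            dens = None
            failing = []
        n_grey = int((labels == GREY).sum())
        keep_mask = labels.isin([m for m in modules if m not in failing])
        removed = int(len(genes) - keep_mask.sum())
        log.append({
            "iteration": iteration,
            "n_genes": int(len(genes)),
            "n_modules": len(modules),
            "n_failing_modules": len(failing),
            "n_grey": n_grey,
            "n_removed": removed,
        })
        if removed == 0 and modules:
            return FilterResult(assignment=labels, network=net,
                                density=dens, log=log, converged=True)
        genes = labels.index[keep_mask]
    warnings.warn(f"density filter did not converge in {max_iter} iterations")
    return FilterResult(assignment=labels, network=net, density=dens,
                        log=log, converged=False)
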