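"""Shared fixtures: small planted two-region datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coexnet as cx


@pytest.fixture(scope="session")
def small_design() -> cx.PlantedDesign:
    """400 genes, 4 modules (2 preserved, 2 region-specific), 160 background."""
    return cx.PlantedDesign(
        n_genes=400,
        module_sizes=(60, 50, 40, 40),
        preserved=(True, True, False, False),
        trait_specs=(),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_design) -> cx.TwoRegionDataset:
    return cx.generate_two_region_dataset(small_design)


@pytest.fixture(scope="session")
def small_network(small_data) -> cx.NetworkMatrices:
    """Signed network (beta=14) of the small dataset's reference region."""
    return cx.build_network(small_data.expr_a, beta=14)


@pytest.fixture(scope="session")
def small_eigengenes(small_data) -> cx.EigengeneSet:
    return cx.module_eigengenes(small_data.expr_a, small_data.truth_a)


def random_adjacency(n: int, seed: int) -> pd.DataFrame:
    """A random valid signed-style adjacency: symmetric, [0,1], unit diag."""
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(A, index=genes, columns=genes)
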