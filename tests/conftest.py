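import networkx as nx
import numpy as np
import pandas as pd
import pytest

from biofilmnet import (
    SyntheticSpec,
    correlation_matrix,
    generate_community,
    soft_threshold_adjacency,
    topological_overlap,
)
from biofilmnet.graphstats import ModuleGraph


@pytest.fixture
def two_module_community():
    """25 taxa (2 planted modules of 10 + 5 background), 150 samples."""
    spec = SyntheticSpec(
        n_taxa=25,
        n_samples=150,
        module_sizes=(10, 10),
        background_taxa=5,
        within_module_cor=0.8,
        noise_sd=0.3,
        trait_loadings={0: 2.0},
        seed=42,
    )
    return generate_community(spec)


@pytest.fixture
def two_module_network(two_module_community):
    matrix, _ = two_module_community
    cor = correlation_matrix(matrix)
    return topological_overlap(soft_threshold_adjacency(cor, 6))


@pytest.fixture
def star_graph():
    return ModuleGraph(graph=nx.star_graph(4), color="star", threshold=0.5)


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric adjacency in [0, 1] with unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def frame(arr, prefix_r="t", prefix_c="s") -> pd.DataFrame:
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])],
    )
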