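"""Module-level simple graphs and their global descriptors.

A module's weighted subnetwork (TOM or adjacency weights) is thresholded
into an undirected simple graph, on which the standard global descriptors
are computed: mean clustering coefficient, degree centralization, density,
average number of neighbors and node count. Density is a normalized version
of the average neighbor count: density = avg_neighbors / (n - 1), an exact
identity for every simple graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ModuleGraph:
    """Unweighted simple graph for one module plus its provenance.

    ``graph`` is an undirected networkx graph over the module's taxa
    (isolated nodes included); ``threshold`` and ``weight_source`` record
    how edges were derived from the weighted network.
    """

    graph: nx.Graph
    color: str | None = None
    threshold: float | None = None
    weight_source: str | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class NetworkStats:
    """Global descriptors of one module graph (Table-style row)."""

    clustering_coefficient: float
    centralization: float
    density: float
    avg_neighbors: float
    n_nodes: int
    color: str | None = None
    threshold: float | None = None

    def as_row(self) -> dict:
        return {
            "module": self.color,
            "clustering_coefficient": self.clustering_coefficient,
            "centralization": self.centralization,
            "density": self.density,
            "avg_neighbors": self.avg_neighbors,
            "n_nodes": self.n_nodes,
            "edge_threshold": self.threshold,
        }


def threshold_for_density(
    weights: np.ndarray, n: int, target_density: float
) -> float:
    """Edge-weight cutoff making a module graph hit a target density.

    Given the off-diagonal weights of an n-node module, returns the weight
    of the round(target * n(n-1)/2)-th largest pair, so thresholding at ">="
    that value yields approximately the target density.
    """
    if not (0.0 < target_density <= 1.0):
        raise ValueError(f"target density must be in (0, 1], got {target_density}")
    n_pairs = n * (n - 1) // 2
    n_edges = int(round(target_density * n_pairs))
    n_edges = max(1, min(n_edges, n_pairs))
    flat = np.sort(weights, kind="stable")[::-1]
    return float(flat[n_edges - 1])


def binarize_module(
    net,
    partition,
    color: str,
    threshold: float | None = None,
    weight_source: str = "tom",
    target_density: float | None = None,
) -> ModuleGraph:
    """Threshold a module's weighted subnetwork into a simple graph.

    Nodes are the taxa of the given module color; an edge joins two taxa
    whose weight (TOM by default, adjacency via ``weight_source="adjacency"``)
    is >= ``threshold``. Alternatively ``target_density`` picks the
    threshold that realizes (approximately) that edge density. The threshold
    used is always recorded on the returned graph.
    """
    members = partition.members(color)
    if not members:
        raise ValueError(f"module {color!r} is empty")
    if weight_source == "tom":
        if net.tom is None:
            raise ValueError("TOM not computed on this network")
        w = net.tom_frame().loc[members, members].to_numpy()
    elif weight_source == "adjacency":
        w = net.adjacency_frame().loc[members, members].to_numpy()
    else:
        raise ValueError(f"unknown weight source {weight_source!r}")
    m = len(members)
    iu = np.triu_indices(m, k=1)
    if threshold is None:
        if target_density is None:
            raise ValueError("provide either threshold or target_density")
        if m < 2:
            threshold = 1.0
        else:
            threshold = threshold_for_density(w[iu], m, target_density)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(members)
    for a, b, val in zip(iu[0], iu[1], w[iu]):
        if val >= threshold:
            g.add_edge(members[a], members[b], weight=float(val))
    return ModuleGraph(
        graph=g, color=color, threshold=float(threshold), weight_source=weight_source
    )


def clustering_coefficient(g: ModuleGraph) -> tuple[pd.Series, float]:
    """Per-node clustering coefficient C_n = 2 e_n / (k_n (k_n - 1)).

    ``e_n`` counts edges among the neighbors of n; nodes with fewer than two
    neighbors have C_n = 0. The network value is the mean over all nodes.
    """
    cc = nx.clustering(g.graph)
    per_node = pd.Series(cc, name="clustering_coefficient").sort_index()
    return per_node, float(per_node.mean()) if len(per_node) else 0.0


def n_nodes(g: ModuleGraph) -> int:
    return g.graph.number_of_nodes()


def avg_neighbors(g: ModuleGraph) -> float:
    """Average connectivity 2E / n (isolated nodes included)."""
    n = g.graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return 2.0 * g.graph.number_of_edges() / n


def density(g: ModuleGraph) -> float:
    """Edge density 2E / (n (n - 1)) = avg_neighbors / (n - 1)."""
    n = g.graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"density undefined for a graph with {n} node(s)")
    return 2.0 * g.graph.number_of_edges() / (n * (n - 1))


def centralization(g: ModuleGraph) -> float:
    """Degree centralization (n / (n - 2)) * (k_max / (n - 1) - density).

    Close to 1 for star-like topologies, close to 0 for decentralized
    (degree-homogeneous) ones.
    """
    n = g.graph.number_of_nodes()
    if n < 3:
        raise ValueError(f"centralization undefined for a graph with {n} node(s)")
    k_max = max(dict(g.graph.degree).values())
    return (n / (n - 2.0)) * (k_max / (n - 1.0) - density(g))


def network_stats(g: ModuleGraph) -> NetworkStats:
    """All global descriptors of one module graph."""
    _, cc = clustering_coefficient(g)
    return NetworkStats(
        clustering_coefficient=cc,
        centralization=centralization(g),
        density=density(g),
        avg_neighbors=avg_neighbors(g),
        n_nodes=n_nodes(g),
        color=g.color,
        threshold=g.threshold,
    )


def stats_table(graphs: list[ModuleGraph]) -> pd.DataFrame:
    """One descriptor row per module graph."""
    return pd.DataFrame([network_stats(g).as_row() for g in graphs])
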