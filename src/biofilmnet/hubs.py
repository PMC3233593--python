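"""Hub (candidate keystone taxon) identification within module graphs.

Four node scores are computed: degree, (unnormalized) betweenness
centrality, Maximum Neighborhood Component (MNC, the size of the largest
connected component among a node's neighbors) and Density of Maximum
Neighborhood Component (DMNC, the edge count of that component divided by
its node count to the power epsilon = 1.7). The double screening scheme
(DSS) first keeps the top-k nodes by MNC and then the top nodes by DMNC
among them, surfacing locally dense hubs that plain degree ranking misses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from biofilmnet.graphstats import ModuleGraph

#: DMNC size exponent from the published hub-screening defaults
DMNC_EPSILON = 1.7


@dataclass
class HubRanking:
    """Per-node centrality scores and the DSS hub selection.

    ``table`` has one row per node with degree, betweenness, MNC, DMNC and
    a ``dss_hub`` flag; ``dss_hubs`` lists the selected hubs in rank order.
    Ties break by degree (descending) then node id (ascending).
    """

    table: pd.DataFrame
    dss_hubs: list[str]
    k_mnc: int
    k_dmnc: int


def degree_centrality(g: ModuleGraph) -> pd.Series:
    """Neighbor count per node."""
    return pd.Series(dict(g.graph.degree), name="degree").sort_index()


def betweenness_centrality(g: ModuleGraph, normalized: bool = False) -> pd.Series:
    """Shortest-path betweenness per node.

    Unnormalized by default: for each unordered pair s != t (counted once),
    the fraction of shortest s-t paths passing through the node.
    Disconnected pairs contribute zero.
    """
    bc = nx.betweenness_centrality(g.graph, normalized=normalized)
    return pd.Series(bc, name="betweenness").sort_index()


def _max_neighborhood_component(g: nx.Graph, node) -> nx.Graph:
    """Largest connected component of the neighbor-induced subgraph."""
    nbrs = list(g.neighbors(node))
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    comps = sorted(
        nx.connected_components(sub),
        key=lambda c: (-len(c), -sub.subgraph(c).number_of_edges(), min(c)),
    )
    return sub.subgraph(comps[0])


def mnc(g: ModuleGraph, node) -> int:
    """Maximum Neighborhood Component: node count of the largest connected
    component among the node's neighbors (the node itself excluded)."""
    return _max_neighborhood_component(g.graph, node).number_of_nodes()


def dmnc(g: ModuleGraph, node) -> float:
    """Density of the Maximum Neighborhood Component: E* / V*^epsilon over
    the largest neighbor component, with epsilon = 1.7; zero when the
    component has no edges."""
    comp = _max_neighborhood_component(g.graph, node)
    v = comp.number_of_nodes()
    e = comp.number_of_edges()
    if v == 0 or e == 0:
        return 0.0
    return e / math.pow(v, DMNC_EPSILON)


def dss_rank(
    g: ModuleGraph, k_mnc: int | None = None, k_dmnc: int | None = None
) -> HubRanking:
    """Double screening scheme hub selection.

    First screen: top ``k_mnc`` nodes by MNC. Second screen: top ``k_dmnc``
    of those by DMNC. Defaults: k_mnc = ceil(n/2), k_dmnc = ceil(n/4). Ties
    break by degree (descending) then lexicographic node id, so the ranking
    is deterministic and stable under relabeling up to that rule.
    """
    nodes = g.nodes
    n = len(nodes)
    if k_mnc is None:
        k_mnc = math.ceil(n / 2)
    if k_dmnc is None:
        k_dmnc = math.ceil(n / 4)
    if not (1 <= k_dmnc <= k_mnc <= n):
        raise ValueError(
            f"need 1 <= k_dmnc <= k_mnc <= n_nodes, got "
            f"k_dmnc={k_dmnc}, k_mnc={k_mnc}, n={n}"
        )
    deg = degree_centrality(g)
    bet = betweenness_centrality(g)
    mnc_s = pd.Series({v: mnc(g, v) for v in nodes}, name="mnc")
    dmnc_s = pd.Series({v: dmnc(g, v) for v in nodes}, name="dmnc")

    screen1 = sorted(nodes, key=lambda v: (-mnc_s[v], -deg[v], str(v)))[:k_mnc]
    screen2 = sorted(screen1, key=lambda v: (-dmnc_s[v], -deg[v], str(v)))[:k_dmnc]

    table = pd.DataFrame(
        {
            "degree": deg,
            "betweenness": bet,
            "mnc": mnc_s,
            "dmnc": dmnc_s,
        }
    )
    table["dss_hub"] = table.index.isin(screen2)
    return HubRanking(table=table, dss_hubs=screen2, k_mnc=k_mnc, k_dmnc=k_dmnc)
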