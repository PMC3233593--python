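"""Rule-based nomination of cultivable helper species.

Uncultivated taxa can sometimes be grown in co-culture with a "helper"
species they co-occur with. Given module partitions from one or more sample
clusters, candidates for a target taxon are the cultivable species that
share the target's module in at least ``required_clusters`` of them, ranked
by: a direct network edge to the target first, then the number of clusters
of co-occurrence, then centrality (betweenness by default), with
lexicographic taxon id as the final deterministic tie-break.

Enrichment success is scored by qPCR relative quantification:
fold-change = 2^-(Ct_experiment - Ct_control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from biofilmnet.graphstats import ModuleGraph
from biofilmnet.hubs import HubRanking
from biofilmnet.modules import ModulePartition


@dataclass
class HelperCandidate:
    """One ranked helper nominee for a target taxon."""

    taxon: str
    n_cofound_clusters: int
    direct_edge: bool
    centrality_score: float
    rank: int

    def as_row(self) -> dict:
        return {
            "taxon": self.taxon,
            "rank": self.rank,
            "direct_edge": self.direct_edge,
            "n_cofound_clusters": self.n_cofound_clusters,
            "centrality_score": self.centrality_score,
        }


def _colors_of(partition) -> pd.Series:
    if isinstance(partition, ModulePartition):
        return partition.colors
    return pd.Series(partition)


def candidate_helpers(
    partitions: Mapping[str, ModulePartition | Mapping[str, str]],
    target_taxon: str,
    cultivability: Mapping[str, bool],
    required_clusters: int = 1,
    module_graphs: Mapping[str, ModuleGraph] | None = None,
    hub_rankings: Mapping[str, HubRanking | pd.Series] | None = None,
) -> list[HelperCandidate]:
    """Rank cultivable co-occurring taxa as helpers for a target.

    Parameters
    ----------
    partitions:
        Sample-cluster name -> module partition (or plain taxon -> color
        mapping). A taxon is "associated" with the target in a cluster when
        it carries the target's module color there.
    module_graphs:
        Optional cluster -> the target module's simple graph; provides the
        direct-edge criterion.
    hub_rankings:
        Optional cluster -> HubRanking (or a plain betweenness Series);
        a candidate's centrality score is its maximum across clusters.
    required_clusters:
        Minimum number of clusters in which a candidate must share the
        target's module.
    """
    if not partitions:
        raise ValueError("no partitions given")
    found_anywhere = False
    n_cofound: dict[str, int] = {}
    direct: dict[str, bool] = {}
    centrality: dict[str, float] = {}

    for cluster, part in partitions.items():
        colors = _colors_of(part)
        if target_taxon not in colors.index:
            continue
        found_anywhere = True
        tcolor = colors[target_taxon]
        mates = colors.index[(colors == tcolor) & (colors.index != target_taxon)]
        graph = None
        if module_graphs and cluster in module_graphs:
            graph = module_graphs[cluster].graph
        ranking = hub_rankings.get(cluster) if hub_rankings else None
        bet = None
        if isinstance(ranking, HubRanking):
            bet = ranking.table["betweenness"]
        elif ranking is not None:
            bet = pd.Series(ranking)
        for taxon in mates:
            n_cofound[taxon] = n_cofound.get(taxon, 0) + 1
            if graph is not None and graph.has_edge(target_taxon, taxon):
                direct[taxon] = True
            if bet is not None and taxon in bet.index:
                centrality[taxon] = max(
                    centrality.get(taxon, 0.0), float(bet[taxon])
                )

    if not found_anywhere:
        raise ValueError(
            f"target taxon {target_taxon!r} is absent from every partition"
        )

    eligible = [
        t
        for t, n in n_cofound.items()
        if n >= required_clusters and cultivability.get(t, False)
    ]
    eligible.sort(
        key=lambda t: (
            not direct.get(t, False),
            -n_cofound[t],
            -centrality.get(t, 0.0),
            t,
        )
    )
    return [
        HelperCandidate(
            taxon=t,
            n_cofound_clusters=n_cofound[t],
            direct_edge=direct.get(t, False),
            centrality_score=centrality.get(t, 0.0),
            rank=i + 1,
        )
        for i, t in enumerate(eligible)
    ]


def relative_quantification(ct_experiment: float, ct_control: float) -> float:
    """qPCR fold-change 2^-(Ct_experiment - Ct_control).

    A target amplifying 3 cycles earlier than the control corresponds to a
    2^3 = 8-fold enrichment. Exactly inverse-symmetric:
    f(a, b) * f(b, a) = 1.
    """
    if not (math.isfinite(ct_experiment) and math.isfinite(ct_control)):
        raise ValueError(
            f"Ct values must be finite, got {ct_experiment}, {ct_control}"
        )
    return 2.0 ** (-(ct_experiment - ct_control))
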