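"""Reading and writing the pipeline's interchange formats.

Abundance matrices travel as TSV/CSV with taxa as rows, samples as columns
and "NA" for missing entries; square matrices (correlation, adjacency, TOM)
as TSV with identical row/column labels; graphs as Cytoscape-readable SIF,
GraphML, or a weighted edge-list TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

SIF_INTERACTION = "co"  # co-occurrence


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples abundance matrix (TSV or CSV, NA = missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA"])

def write_abundance(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    matrix.to_csv(path, sep=_sep_for(path), na_rep="NA")


read_square_matrix = read_abundance
write_square_matrix = write_abundance


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a samples x traits table (CSV by default)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe -> species TSV (no header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns: probe, species")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_probe_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(mapping.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    if hasattr(graph, "graph") and isinstance(graph.graph, nx.Graph):
        return graph.graph  # ModuleGraph
    if hasattr(graph, "adjacency"):  # WeightedNetwork: complete weighted graph
        g = nx.Graph()
        taxa = graph.taxa
        g.add_nodes_from(taxa)
        a = graph.adjacency
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                if a[i, j] > 0:
                    g.add_edge(taxa[i], taxa[j], weight=float(a[i, j]))
        return g
    raise TypeError(f"cannot export object of type {type(graph).__name__}")


def export_graph(graph, path: str | Path, fmt: str | None = None) -> Path:
    """Export a graph as SIF, GraphML, or a weighted edge-list TSV.

    ``fmt`` defaults to the file extension (.sif / .graphml / .tsv). SIF
    lines are ``node<TAB>co<TAB>node`` (one per edge), with isolated nodes
    written as bare single-column lines so they survive the round trip.
    """
    path = Path(path)
    g = _as_nx(graph)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(g.edges):
                fh.write(f"{u}\t{SIF_INTERACTION}\t{v}\n")
            for node in sorted(n for n in g.nodes if g.degree(n) == 0):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt in ("tsv", "edgelist"):
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown graph export format {fmt!r}")
    return path


def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF file back into an undirected graph."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                source, _, targets = parts[0], parts[1], parts[2:]
                for t in targets:
                    g.add_edge(source, t)
    return g


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return g
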