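"""Regulatory-network assembly, connectivity summary and graph export.

Ranked TF-TG predictions from the per-cluster analyses are combined
into one directed graph; a TF's connectivity is the number of distinct
targets it retains above a confidence cutoff, and the top-connectivity
TFs are the network hubs.  Graphs are written as SIF or GraphML for
downstream viewers such as Cytoscape.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "summarize_connectivity",
    "build_network",
    "export_network",
    "read_network",
]

EDGE_COLUMNS = ["tf", "gene", "confidence", "cluster"]


def summarize_connectivity(edges: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Per-TF connectivity at a confidence cutoff.

    ``edges`` holds one row per predicted (tf, gene) per source cluster
    with columns ``tf``, ``gene``, ``confidence`` and ``cluster``.  A
    target predicted for the same TF in several clusters counts once in
    the ``total`` (distinct targets) but appears in each per-cluster
    column, so per-cluster counts may sum to more than the total.
    Sorted by descending total, ties by TF identifier.
    """
    kept = edges[edges["confidence"] >= cutoff]
    clusters = sorted(edges["cluster"].unique()) if "cluster" in edges else []
    rows = []
    for tf in sorted(edges["tf"].unique()):
        sub = kept[kept["tf"] == tf]
        row: dict[str, object] = {"tf": tf, "total": sub["gene"].nunique()}
        for c in clusters:
            row[str(c)] = int(sub.loc[sub["cluster"] == c, "gene"].nunique())
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["tf", "total"])
    return (
        out.sort_values(["total", "tf"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def build_network(
    edges: pd.DataFrame,
    cutoff: float = 0.5,
    top_k_tfs: int | None = None,
) -> nx.DiGraph:
    """Directed TF -> target network above a confidence cutoff.

    Edge attributes: ``confidence`` (the maximum over predicting
    clusters), ``clusters`` (comma-joined sorted source cluster ids) and
    ``frequency`` (how many clusters predicted the edge).  With
    ``top_k_tfs`` set, only the k highest-connectivity hub TFs are kept
    (ties broken by TF identifier).
    """
    kept = edges[edges["confidence"] >= cutoff].copy()
    if top_k_tfs is not None:
        summary = summarize_connectivity(edges, cutoff=cutoff)
        hubs = set(summary["tf"].head(max(top_k_tfs, 0)))
        kept = kept[kept["tf"].isin(hubs)]
    g = nx.DiGraph()
    if kept.empty:
        return g
    grouped = kept.groupby(["tf", "gene"])
    for (tf, gene), sub in grouped:
        clusters = sorted(str(c) for c in sub["cluster"].unique()) if "cluster" in sub else []
        g.add_node(tf, kind="TF")
        if gene not in g or g.nodes[gene].get("kind") != "TF":
            g.add_node(gene, kind=g.nodes[gene].get("kind", "target") if gene in g else "target")
        g.add_edge(
            tf,
            gene,
            confidence=float(sub["confidence"].max()),
            clusters=",".join(clusters),
            frequency=len(clusters) if clusters else 1,
        )
    return g


def export_network(network: nx.DiGraph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as SIF (``TF regulates gene``) or GraphML."""
    path = Path(path)
    if fmt == "sif":
        lines = [f"{u}\tregulates\t{v}" for u, v in sorted(network.edges())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}; expected 'sif' or 'graphml'")
    return path


def read_network(path: str | Path, fmt: str = "graphml") -> nx.DiGraph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path, node_type=str)
    if fmt == "sif":
        g = nx.DiGraph()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            u, _, v = line.split("\t")
            g.add_edge(u, v)
        return g
    raise ValueError(f"unknown network format {fmt!r}")
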