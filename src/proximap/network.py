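"""Bait-prey interaction networks and prey-prey augmentation.

The BioID map is a star graph per bait (bait -> each of its preys); shared
preys connect multiple baits. Augmentation adds prey-prey edges from
interaction-database exports, but only between proteins already in the
network (the node set never changes). Edges are undirected, symbol-pair
canonicalised, and carry the union of their provenance tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .ingest import Interactome


def build_network(interactomes: Mapping[str, Interactome]) -> nx.Graph:
    """Star graph of bait-prey edges with provenance tag ``bioid``.

    Node attribute ``role`` is ``bait`` or ``prey`` (a prey that is also a
    bait keeps the bait role). Self-loops (a bait detecting itself) are
    dropped to keep the graph simple.
    """
    if not interactomes:
        raise ValueError("at least one interactome is required")
    g = nx.Graph()
    for bait in interactomes:
        g.add_node(bait, role="bait")
    for bait, inter in interactomes.items():
        for prey in inter.preys:
            if prey == bait:
                continue
            if prey not in g:
                g.add_node(prey, role="prey")
            if g.has_edge(bait, prey):
                g.edges[bait, prey]["sources"].add("bioid")
            else:
                g.add_edge(bait, prey, sources={"bioid"})
    return g


def augment(
    network: nx.Graph,
    edge_tables: Sequence[tuple[str, Iterable[tuple[str, str]]]],
) -> nx.Graph:
    """Add prey-prey edges whose BOTH endpoints already exist in the network.

    ``edge_tables`` is a list of (source tag, symbol-pair iterable). Duplicate
    edges are merged and their provenance tags unioned; the node set is
    unchanged. Returns a new graph.
    """
    g = network.copy()
    # symbols are expected in the ingest namespace already (reader-normalized)
    for tag, edges in edge_tables:
        provenance = f"database:{tag}"
        for a, b in edges:
            a, b = sorted((a, b))
            if a == b or a not in g or b not in g:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["sources"].add(provenance)
            else:
                g.add_edge(a, b, sources={provenance})
    return g


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    """GraphML export (provenance sets serialised as ';'-joined strings)."""
    g = network.copy()
    for _, _, data in g.edges(data=True):
        data["sources"] = ";".join(sorted(data["sources"]))
    nx.write_graphml(g, str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Simple edge-list TSV (node_a, node_b, sources) importable by Cytoscape."""
    rows = [
        {"node_a": a, "node_b": b, "sources": ";".join(sorted(d["sources"]))}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "sources"]).to_csv(
        path, sep="\t", index=False
    )
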