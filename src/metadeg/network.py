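"""Interaction-network handling: edge-list / SIF ingestion, merging, and
largest-connected-module extraction of a DEG set.

Networks are undirected simple graphs over gene symbols; node identity is
exact, case-sensitive string match.  Direction annotations in source files
are discarded; self-loops and duplicate (including reversed) edges are
dropped with logged counts.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Set

import networkx as nx

logger = logging.getLogger(__name__)


def load_edge_list(path, dialect: str = "tsv2col") -> nx.Graph:
    """Read an undirected network from a two-column edge list or a SIF file.

    ``tsv2col``: whitespace/tab-separated lines with at least two fields;
    the first two are the edge endpoints.  ``sif``: ``source relation
    target1 [target2 ...]`` fan-out lines; a single-field line declares an
    isolated node.  Malformed lines raise with their line number.
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    g = nx.Graph()
    n_self, n_dup = 0, 0

    def add_edge(u: str, v: str):
        nonlocal n_self, n_dup
        if u == v:
            n_self += 1
            g.add_node(u)
            return
        if g.has_edge(u, v):
            n_dup += 1
            return
        g.add_edge(u, v)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if dialect == "tsv2col":
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two columns, got {len(fields)}"
                    )
                add_edge(fields[0], fields[1])
            else:  # sif
                if len(fields) == 1:
                    g.add_node(fields[0])
                elif len(fields) == 2:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line with a relation but no target"
                    )
                else:
                    src = fields[0]
                    for target in fields[2:]:
                        add_edge(src, target)
    if n_self or n_dup:
        logger.info(
            "load_edge_list %s: dropped %d self-loops, %d duplicate edges",
            path, n_self, n_dup,
        )
    return g


def merge_networks(nets: List[nx.Graph]) -> nx.Graph:
    """Union of nodes and edges across networks (simple-graph invariants kept)."""
    if not nets:
        raise ValueError("need at least one network")
    merged = nx.Graph()
    for net in nets:
        merged.add_nodes_from(net.nodes)
        merged.add_edges_from((u, v) for u, v in net.edges if u != v)
    return merged


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a deterministic two-column edge list (sorted endpoints/lines)."""
    lines = sorted(tuple(sorted((u, v))) for u, v in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with open(path, "w") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\t{n}\n")  # read back as an isolated node


def biggest_connected_deg_module(net: nx.Graph, degs: Iterable[str]) -> Set[str]:
    """Node set of the largest connected component of the DEG-induced subgraph.

    DEGs absent from the network are ignored (logged).  Component ties
    break deterministically by (size, then lexicographically smallest
    member).  An empty intersection yields an empty set with a warning.
    """
    degs = set(degs)
    present = degs & set(net.nodes)
    n_absent = len(degs) - len(present)
    if n_absent:
        logger.info("biggest_connected_deg_module: %d DEGs absent from network", n_absent)
    if not present:
        logger.warning("biggest_connected_deg_module: no DEGs present in network")
        return set()
    sub = net.subgraph(present)
    components = sorted(
        nx.connected_components(sub), key=lambda c: (-len(c), min(c))
    )
    return set(components[0])
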