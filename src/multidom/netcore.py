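"""Graph data model and edge-list I/O for multilayer dominating-set analysis.

Graphs are simple undirected :class:`networkx.Graph` objects over opaque
string node identifiers. A multilayer network is an ordered collection of
such graphs whose node sets may overlap partially; layers are never
physically coupled (there are no inter-layer edges anywhere in the model).

All deterministic iteration in this package uses lexicographic order of the
string identifiers, which makes preprocessing scans and tie-breaking
reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "UndirectedGraph",
    "MultilayerNetwork",
    "GraphValidationError",
    "EdgeListParseError",
    "new_graph",
    "validate_graph",
    "read_edge_list",
    "write_edge_list",
    "induced_subgraph",
    "common_nodes",
    "graph_union",
    "degree",
    "sorted_nodes",
]

#: Alias used throughout: a simple undirected graph with string node ids.
UndirectedGraph = nx.Graph


class GraphValidationError(ValueError):
    """Raised when a graph violates the simple-undirected contract."""


class EdgeListParseError(ValueError):
    """Raised on a malformed edge-list line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def new_graph(nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()) -> UndirectedGraph:
    """Build a validated simple graph from node ids and endpoint pairs."""
    g = nx.Graph()
    g.add_nodes_from(str(v) for v in nodes)
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            raise GraphValidationError(f"self-loop on node {u!r}")
        g.add_edge(u, v)
    return g


def validate_graph(g: UndirectedGraph) -> None:
    """Check the simple-undirected invariants; raise GraphValidationError."""
    if g.is_directed() or g.is_multigraph():
        raise GraphValidationError("graph must be simple and undirected")
    loops = list(nx.nodes_with_selfloops(g))
    if loops:
        raise GraphValidationError(f"self-loops present on {sorted(loops)[:5]}")


def sorted_nodes(g: UndirectedGraph) -> list[str]:
    """Node identifiers in lexicographic order (the canonical iteration order)."""
    return sorted(g.nodes)


@dataclass(frozen=True)
class MultilayerNetwork:
    """Ordered collection of N >= 1 uncoupled undirected layers.

    The universe is the union of the layer node sets; layers may cover
    different subsets of it. Domination is always evaluated per layer.
    """

    layers: tuple[UndirectedGraph, ...]
    universe: frozenset[str] = field(init=False)

    def __init__(self, layers: Sequence[UndirectedGraph]):
        layers = tuple(layers)
        if len(layers) < 1:
            raise ValueError("a multilayer network needs at least one layer")
        for g in layers:
            validate_graph(g)
        object.__setattr__(self, "layers", layers)
        object.__setattr__(
            self, "universe", frozenset(itertools.chain.from_iterable(g.nodes for g in layers))
        )

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i: int) -> UndirectedGraph:
        return self.layers[i]


def read_edge_list(path: str | Path) -> UndirectedGraph:
    """Read a plain-text edge list.

    Format: one edge per line as two whitespace-separated tokens (extra
    tokens ignored); a single-token line declares an isolated node; lines
    beginning with ``#`` are comments; duplicate and reversed-duplicate
    edges collapse. Self-loop lines are rejected.
    """
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                g.add_node(tokens[0])
                continue
            u, v = tokens[0], tokens[1]
            if u == v:
                raise EdgeListParseError(f"self-loop {u!r}", lineno)
            g.add_edge(u, v)
    return g


def write_edge_list(g: UndirectedGraph, path: str | Path) -> None:
    """Write a graph so that :func:`read_edge_list` round-trips it exactly.

    Edges are emitted with lexicographically ordered endpoints, one per
    line; isolated nodes are emitted afterwards as single-token lines.
    """
    validate_graph(g)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")
        for v in sorted_nodes(g):
            if g.degree(v) == 0:
                fh.write(f"{v}\n")


def induced_subgraph(g: UndirectedGraph, keep: Iterable[str]) -> UndirectedGraph:
    """Subgraph induced by ``keep`` (ids absent from g are ignored)."""
    keep = set(keep) & set(g.nodes)
    return nx.Graph(g.subgraph(keep))


def common_nodes(g1: UndirectedGraph, g2: UndirectedGraph) -> set[str]:
    """V_1 ∩ V_2 — the shared node universe of two layers."""
    return set(g1.nodes) & set(g2.nodes)


def graph_union(g1: UndirectedGraph, g2: UndirectedGraph) -> UndirectedGraph:
    """Single graph with node set V_1 ∪ V_2 and edge set E_1 ∪ E_2."""
    u = nx.Graph()
    u.add_nodes_from(g1.nodes)
    u.add_nodes_from(g2.nodes)
    u.add_edges_from(g1.edges)
    u.add_edges_from(g2.edges)
    return u


def degree(g: UndirectedGraph, v: str) -> int:
    """Number of edges incident to v; raises KeyError for unknown nodes."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return g.degree(v)
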