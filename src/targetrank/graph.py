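"""The deduplicated symmetric interactome graph.

Physical protein-protein interactions are symmetric, but the random-walk
machinery consumes a *directed* edge list, so the graph is stored as the
symmetric closure of the cleaned pairs: for every interaction (a, b) both
(a, b) and (b, a) are present exactly once, and a self-interaction (a, a)
is present exactly once.  Degree of a vertex is its out-degree in this
closure — a self-loop therefore contributes 1, not 2.  Vertices are
induced by the edge list (no isolated vertices exist).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import networkx as nx

from .mitab import AccessionPair

__all__ = [
    "Interactome",
    "GraphSummary",
    "AsymmetricEdgeListError",
    "build_graph",
    "read_edge_list",
    "write_edge_list",
    "graph_summary",
]


@dataclass(frozen=True)
class Interactome:
    """Symmetric directed-edge closure with its degree map."""

    vertices: frozenset[str]
    directed_edges: frozenset[tuple[str, str]]
    degree: dict[str, int]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_directed_edges(self) -> int:
        return len(self.directed_edges)

    def out_neighbors(self) -> dict[str, list[str]]:
        """Adjacency as sorted out-neighbour lists."""
        adj: dict[str, list[str]] = {v: [] for v in self.vertices}
        for a, b in self.directed_edges:
            adj[a].append(b)
        for v in adj:
            adj[v].sort()
        return adj


class AsymmetricEdgeListError(ValueError):
    """An edge list claiming to be a symmetric closure is missing a reverse."""


def build_graph(pairs: Iterable[AccessionPair]) -> Interactome:
    """Build the symmetric, deduplicated closure of an interaction list.

    For each pair (a, b) the reverse (b, a) is added (also when a == b),
    then all multiplicities are removed, so for a != b both directions
    appear once and a self-pair yields a single (a, a) edge.  The result
    is independent of input order and of the orientation of each pair.
    """
    edges: set[tuple[str, str]] = set()
    for p in pairs:
        edges.add((p.a, p.b))
        edges.add((p.b, p.a))
    return _from_edge_set(edges)


def _from_edge_set(edges: set[tuple[str, str]]) -> Interactome:
    degree: dict[str, int] = {}
    vertices: set[str] = set()
    for a, b in edges:
        vertices.add(a)
        vertices.add(b)
        degree[a] = degree.get(a, 0) + 1
    for v in vertices:
        degree.setdefault(v, 0)
    return Interactome(frozenset(vertices), frozenset(edges), degree)


def read_edge_list(stream: Iterable[str]) -> Interactome:
    """Read a two-column directed edge list that is already a symmetric closure.

    Each non-empty line holds exactly two whitespace-separated tokens.
    Duplicate lines are collapsed.  If some (a, b) with a != b lacks its
    reverse (b, a) the file is not a valid closure and is rejected with a
    diagnostic naming the first offending pair (in lexicographic order).
    """
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected 2 tokens, found {len(tokens)}")
        edges.add((tokens[0], tokens[1]))
    for a, b in sorted(edges):
        if a != b and (b, a) not in edges:
            raise AsymmetricEdgeListError(
                f"edge ({a}, {b}) present without its reverse ({b}, {a})"
            )
    return _from_edge_set(edges)


def write_edge_list(g: Interactome, sink: TextIO) -> None:
    """Write the directed edges in canonical (lexicographic) order."""
    for a, b in sorted(g.directed_edges):
        sink.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class GraphSummary:
    n_vertices: int
    n_directed_edges: int
    n_loops: int
    n_components: int
    max_degree: int


def graph_summary(g: Interactome) -> GraphSummary:
    """Headline counts of the graph (loops and components included)."""
    if not g.vertices:
        return GraphSummary(0, 0, 0, 0, 0)
    ug = nx.Graph()
    ug.add_nodes_from(g.vertices)
    ug.add_edges_from(g.directed_edges)
    return GraphSummary(
        n_vertices=g.n_vertices,
        n_directed_edges=g.n_directed_edges,
        n_loops=sum(1 for a, b in g.directed_edges if a == b),
        n_components=nx.number_connected_components(ug),
        max_degree=max(g.degree.values()),
    )
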