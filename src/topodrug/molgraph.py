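"""Hydrogen-suppressed molecular graphs and their edge partitions.

A molecule is modelled as a simple connected undirected graph: vertices are
heavy atoms, edges are topological adjacencies (bond order is ignored —
this is the convention under which the published polynomial edge counts
match the drug skeletons).  Two edge partitions drive everything
downstream:

* ``degree``: edges classed by the sorted pair of endpoint degrees
  ``(d_u, d_v)``;
* ``neighborhood``: edges classed by the sorted pair of endpoint
  neighbor-degree sums ``(S_u, S_v)``, where ``S_v`` is the sum of the
  degrees of the neighbors of ``v``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GraphFormatError",
    "MolecularGraph",
    "EdgePartition",
    "load_graph",
    "parse_edgelist",
    "vertex_degrees",
    "neighbor_degree_sums",
    "edge_partition",
]


class GraphFormatError(ValueError):
    """Raised for malformed or invalid edge-list input."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class MolecularGraph:
    """A validated simple connected graph of heavy atoms.

    Vertices are normalized to consecutive integers ``0..n-1`` regardless
    of the labels used in the input file.  ``element_label`` is purely
    informational and never enters any index computation.
    """

    name: str
    graph: nx.Graph
    element_label: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise GraphFormatError("graph has no vertices")
        if any(u == v for u, v in g.edges):
            raise GraphFormatError("self-loops are not allowed")
        if not nx.is_connected(g):
            raise GraphFormatError("graph is not connected")

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[int, int]]:
        return self.graph.edges()


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of ``(k, l)`` edge classes with counts ``m_kl``.

    ``kind`` records whether the pair is endpoint degrees or endpoint
    neighbor-degree sums.  Keys are stored sorted, ``k <= l``.
    """

    kind: str
    classes: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        if self.kind not in ("degree", "neighborhood"):
            raise ValueError(f"unknown partition kind {self.kind!r}")
        for (k, l), m in self.classes.items():
            if k > l:
                raise ValueError(f"class key {(k, l)} not sorted")
            if k < 1 or m < 1:
                raise ValueError(f"invalid class {(k, l)}: {m}")

    @property
    def n_edges(self) -> int:
        return sum(self.classes.values())

    def as_dict(self) -> dict[tuple[int, int], int]:
        return dict(self.classes)


def parse_edgelist(text: str, name: str = "") -> MolecularGraph:
    """Parse the edge-list dialect into a validated :class:`MolecularGraph`.

    Dialect: ``#`` starts a comment; an optional ``name <string>`` line; an
    optional ``atom <id> <symbol>`` line per vertex; one ``edge`` per line
    as two whitespace-separated positive integers (a leading literal
    ``edge`` keyword is accepted and ignored).
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    labels: dict[int, str] = {}
    graph_name = name
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "name":
            if len(parts) < 2:
                raise GraphFormatError("'name' line needs a value", lineno)
            graph_name = " ".join(parts[1:])
            continue
        if parts[0] == "atom":
            if len(parts) != 3:
                raise GraphFormatError("'atom' line needs <id> <symbol>", lineno)
            try:
                labels[int(parts[1])] = parts[2]
            except ValueError:
                raise GraphFormatError(f"bad atom id {parts[1]!r}", lineno) from None
            continue
        if parts[0] == "edge":
            parts = parts[1:]
        if len(parts) != 2:
            raise GraphFormatError(f"expected two vertex ids, got {line!r}", lineno)
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise GraphFormatError(f"non-integer vertex id in {line!r}", lineno) from None
        if u < 1 or v < 1:
            raise GraphFormatError("vertex ids must be positive integers", lineno)
        if u == v:
            raise GraphFormatError(f"self-loop at vertex {u}", lineno)
        key = (min(u, v), max(u, v))
        if key in seen:
            raise GraphFormatError(f"duplicate edge {u} {v}", lineno)
        seen.add(key)
        edges.append((u, v))
    if not edges:
        raise GraphFormatError("no edges found")

    # normalize 1-based (or arbitrary) ids to consecutive 0-based integers
    ids = sorted({v for e in edges for v in e})
    remap = {old: new for new, old in enumerate(ids)}
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    g.add_edges_from((remap[u], remap[v]) for u, v in edges)
    label_map = {remap[i]: s for i, s in labels.items() if i in remap}
    return MolecularGraph(name=graph_name, graph=g, element_label=label_map)


def load_graph(path: str | Path) -> MolecularGraph:
    """Load and validate a molecular graph from an edge-list file."""
    path = Path(path)
    return parse_edgelist(path.read_text(), name=path.stem.split(".")[0])


def vertex_degrees(g: MolecularGraph) -> dict[int, int]:
    """Degree of every vertex; the degrees sum to ``2|E|``."""
    return dict(g.graph.degree())


def neighbor_degree_sums(g: MolecularGraph) -> dict[int, int]:
    """Neighbor-degree sum ``S_v = sum(d_u for u ~ v)`` for every vertex.

    Satisfies the handshake-square identity ``sum_v S_v = sum_v d_v**2``.
    """
    deg = dict(g.graph.degree())
    return {v: sum(deg[u] for u in g.graph.neighbors(v)) for v in g.graph.nodes}


def edge_partition(g: MolecularGraph, kind: str = "neighborhood") -> EdgePartition:
    """Partition the edges of ``g`` into sorted ``(k, l)`` classes.

    ``kind='degree'`` keys each edge by its endpoint degrees,
    ``kind='neighborhood'`` by its endpoint neighbor-degree sums.
    """
    if kind == "degree":
        value = vertex_degrees(g)
    elif kind == "neighborhood":
        value = neighbor_degree_sums(g)
    else:
        raise ValueError(f"unknown partition kind {kind!r}")
    counts = Counter(tuple(sorted((value[u], value[v]))) for u, v in g.edges())
    return EdgePartition(kind=kind, classes=dict(counts))
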