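"""Baseline graph storage and path queries.

The curated baseline network is held as a directed multigraph keyed by
element identity (normalized identifier, element type).  Parallel edges with
different sign or attributes are all retained — each input row becomes
exactly one edge.  Path queries are hop-count shortest-path searches (unit
edge weight) restricted to paths of at least two edges: a direct baseline
edge is never itself a "path".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .model import Element, Interaction, InteractionList, NEGATIVE, POSITIVE

__all__ = ["BaselineGraph", "Path", "build_graph", "find_edges", "shortest_paths", "io_nodes"]

Key = tuple[str, str]


@dataclass(frozen=True)
class Path:
    """An ordered chain of baseline edges; consecutive edges share a node.

    ``net_sign`` composes edge signs multiplicatively: positive iff the
    number of negative edges along the path is even.
    """

    edges: tuple[Interaction, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.edges, self.edges[1:]):
            if a.target.key != b.source.key:
                raise ValueError("path edges are not chained")

    @property
    def length(self) -> int:
        return len(self.edges)

    @property
    def node_keys(self) -> tuple[Key, ...]:
        return (self.edges[0].source.key,) + tuple(e.target.key for e in self.edges)

    @property
    def net_sign(self) -> str:
        negatives = sum(1 for e in self.edges if e.sign == NEGATIVE)
        return POSITIVE if negatives % 2 == 0 else NEGATIVE

    def describe(self) -> str:
        names = [self.edges[0].source.name] + [e.target.name for e in self.edges]
        return " -> ".join(names)


class BaselineGraph:
    """Directed multigraph over element-identity keys.

    Wraps a :class:`networkx.MultiDiGraph` whose nodes are identity keys and
    whose edges carry the originating :class:`Interaction`.  A collapsed
    unit-weight :class:`networkx.DiGraph` is kept alongside for shortest-path
    queries.
    """

    def __init__(self) -> None:
        self.multigraph = nx.MultiDiGraph()
        self.simple = nx.DiGraph()
        self.elements: dict[Key, Element] = {}

    # -- construction -------------------------------------------------
    def add_interaction(self, interaction: Interaction) -> None:
        for element in (interaction.source, interaction.target):
            key = element.key
            if key not in self.elements:
                self.elements[key] = element
                self.multigraph.add_node(key)
                self.simple.add_node(key)
        s, t = interaction.source.key, interaction.target.key
        self.multigraph.add_edge(s, t, interaction=interaction)
        self.simple.add_edge(s, t)

    # -- basic queries ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.multigraph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.multigraph.number_of_edges()

    def has_element(self, element: Element) -> bool:
        return element.key in self.elements

    def edges_between(self, s: Element, t: Element) -> list[Interaction]:
        sk, tk = s.key, t.key
        if not self.multigraph.has_edge(sk, tk):
            return []
        data = self.multigraph.get_edge_data(sk, tk)
        edges = [d["interaction"] for d in data.values()]
        edges.sort(key=lambda e: e.index)
        return edges

    def all_edges(self) -> list[Interaction]:
        edges = [d["interaction"] for _, _, d in self.multigraph.edges(data=True)]
        edges.sort(key=lambda e: e.index)
        return edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"BaselineGraph(nodes={self.n_nodes}, edges={self.n_edges})"


def build_graph(lst: InteractionList) -> BaselineGraph:
    """Build the baseline graph; every input row becomes exactly one edge."""
    g = BaselineGraph()
    for it in lst:
        g.add_interaction(it)
    return g


def find_edges(g: BaselineGraph, s: Element, t: Element) -> list[Interaction]:
    """All parallel baseline edges s -> t whose endpoints element-match s and t.

    Empty when either node is absent.  Directed: (s, t) and (t, s) are
    independent queries.
    """
    return g.edges_between(s, t)


def _edge_paths_for_nodes(
    g: BaselineGraph, node_path: list[Key], max_paths: int
) -> list[Path]:
    """Expand a node-key sequence into concrete edge paths.

    Parallel edges multiply the expansion; per hop they are taken in baseline
    input order, so the overall order is deterministic.
    """
    per_hop: list[list[Interaction]] = []
    for a, b in zip(node_path, node_path[1:]):
        data = g.multigraph.get_edge_data(a, b)
        edges = sorted((d["interaction"] for d in data.values()), key=lambda e: e.index)
        per_hop.append(edges)
    paths = []
    for combo in itertools.product(*per_hop):
        paths.append(Path(edges=tuple(combo)))
        if len(paths) >= max_paths:
            break
    return paths


def shortest_paths(
    g: BaselineGraph,
    s: Element,
    t: Element,
    max_len: int = 6,
    max_paths: int = 10,
) -> list[Path]:
    """All minimum-hop-count paths s ~> t of length >= 2.

    A direct edge s -> t does not count as a path and is excluded from the
    search, so with a direct edge present the shortest *path* is the shortest
    multi-edge route.  Paths longer than ``max_len`` hops are not returned;
    at most ``max_paths`` paths are returned, ordered lexicographically by
    their node-key sequences (parallel-edge expansions in baseline order).

    Both endpoints must be present in the graph and distinct (contract).
    """
    sk, tk = s.key, t.key
    if sk not in g.elements or tk not in g.elements:
        raise ValueError("shortest_paths requires both endpoints in the graph")
    if sk == tk:
        raise ValueError("shortest_paths requires distinct endpoints")
    search = g.simple
    if search.has_edge(sk, tk):
        search = nx.restricted_view(search, [], [(sk, tk)])
    try:
        node_paths = list(nx.all_shortest_paths(search, sk, tk))
    except nx.NetworkXNoPath:
        return []
    node_paths = [p for p in node_paths if 2 <= len(p) - 1 <= max_len]
    node_paths.sort()
    out: list[Path] = []
    for node_path in node_paths:
        out.extend(_edge_paths_for_nodes(g, node_path, max_paths - len(out)))
        if len(out) >= max_paths:
            break
    return out


def io_nodes(g: BaselineGraph) -> tuple[int, int]:
    """(input-node count, output-node count).

    Input nodes have no regulators (in-degree 0); output nodes have no
    downstream targets (out-degree 0).
    """
    inputs = sum(1 for _, d in g.multigraph.in_degree() if d == 0)
    outputs = sum(1 for _, d in g.multigraph.out_degree() if d == 0)
    return inputs, outputs
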