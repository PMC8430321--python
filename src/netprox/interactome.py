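"""Undirected protein–protein interaction graphs and shortest-path primitives.

The interactome is an unweighted, undirected graph over gene identifiers.
Edge confidences (STRING-style combined scores) are used only to filter edges
at load time; all distances are hop counts, because the drug–disease proximity
statistic is defined on unweighted shortest paths.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import MissingNodeError, ParseError
from .genesets import GeneSet, as_members

_SCORE_SCALES = ("unit", "string999")


class Interactome:
    """An undirected simple graph of gene identifiers.

    Invariants: no self-loops, no duplicate (unordered) edges, every edge
    endpoint is a node, and edge confidences — when present — lie in [0, 1].
    Treated as immutable after construction; a CSR adjacency over the sorted
    node order is cached for the numeric routines.
    """

    def __init__(self, graph: nx.Graph | None = None):
        g = graph if graph is not None else nx.Graph()
        g.remove_edges_from(nx.selfloop_edges(g))
        self._g = g
        self._csr_cache: tuple[list[str], dict[str, int], sp.csr_matrix] | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "Interactome":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 3:
                u, v, c = edge
                g.add_edge(u, v, confidence=float(c))
            else:
                u, v = edge
                g.add_edge(u, v)
        return cls(g)

    # -- basic queries -----------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def has_node(self, node: str) -> bool:
        return self._g.has_node(node)

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self, data: bool = False):
        return self._g.edges(data=data)

    def confidence(self, u: str, v: str) -> float | None:
        return self._g.edges[u, v].get("confidence")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    # -- numeric view ------------------------------------------------------
    def csr(self) -> tuple[list[str], dict[str, int], sp.csr_matrix]:
        """Sorted node order, node→index map, and the 0/1 CSR adjacency."""
        if self._csr_cache is None:
            order = sorted(self._g.nodes)
            index = {n: i for i, n in enumerate(order)}
            n = len(order)
            rows, cols = [], []
            for u, v in self._g.edges:
                i, j = index[u], index[v]
                rows += [i, j]
                cols += [j, i]
            adj = sp.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
            )
            self._csr_cache = (order, index, adj)
        return self._csr_cache


@dataclass(frozen=True)
class DistanceMap:
    """Hop distances from a single source; unreachable nodes are absent."""

    source: str
    distances: Mapping[str, int]

    def __getitem__(self, node: str) -> int:
        return self.distances[node]

    def get(self, node: str, default=None):
        return self.distances.get(node, default)


def load_edge_list(
    path: str | Path,
    min_confidence: float = 0.0,
    score_scale: str = "unit",
) -> Interactome:
    """Load a whitespace/tab-delimited edge list, filtering by confidence.

    Columns are ``node_a node_b [score]``; lines starting with ``#`` are
    ignored. With ``score_scale="string999"`` integer STRING combined scores
    (0–999) are divided by 1000 on load. Only edges whose rescaled confidence
    is ≥ ``min_confidence`` are kept; score-less edges survive only when
    ``min_confidence`` is 0. Self-loops and duplicate pairs are dropped.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    if score_scale not in _SCORE_SCALES:
        raise ValueError(f"score_scale must be one of {_SCORE_SCALES}")

    g = nx.Graph()
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(
                    f"expected at least 2 columns, got {len(parts)}", lineno
                )
            u, v = parts[0], parts[1]
            if len(parts) >= 3:
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"non-numeric score {parts[2]!r}", lineno
                    ) from None
                if score_scale == "string999":
                    score /= 1000.0
                if not 0.0 <= score <= 1.0:
                    raise ParseError(
                        f"confidence {score:g} outside [0, 1] after rescaling", lineno
                    )
                if score < min_confidence:
                    g.add_nodes_from((u, v))
                    continue
                if u != v:
                    g.add_edge(u, v, confidence=score)
                else:
                    g.add_node(u)
            else:
                if min_confidence > 0:
                    g.add_nodes_from((u, v))
                    continue
                if u != v:
                    g.add_edge(u, v)
                else:
                    g.add_node(u)
    return Interactome(g)


def write_edge_list(g: Interactome, path: str | Path) -> None:
    """Write a sorted, deterministic edge list (confidence column when present)."""
    lines = []
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        c = g.confidence(u, v)
        if c is None:
            lines.append(f"{u}\t{v}\n")
        else:
            lines.append(f"{u}\t{v}\t{c:g}\n")
    Path(path).write_text("".join(lines))


def bfs_distances(g: Interactome, source: str) -> DistanceMap:
    """Exact hop distances from ``source`` to every reachable node."""
    if not g.has_node(source):
        raise MissingNodeError(f"source node {source!r} not in graph")
    dist = nx.single_source_shortest_path_length(g.graph, source)
    return DistanceMap(source=source, distances=dict(dist))


def induced_subgraph(
    g: Interactome, genes: GeneSet | Iterable[str]
) -> tuple[Interactome, list[str]]:
    """Subgraph on ``g.nodes ∩ genes``; also returns the sorted missing genes."""
    members = as_members(genes)
    present = members & g.nodes
    missing = sorted(members - present)
    sub = Interactome(nx.Graph(g.graph.subgraph(present)))
    return sub, missing


def largest_connected_component(g: Interactome) -> Interactome:
    """The component with the most nodes; ties go to the one whose smallest
    member id sorts first."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    components = nx.connected_components(g.graph)
    best = max(components, key=lambda c: (len(c), _neg_lex(min(c))))
    return Interactome(nx.Graph(g.graph.subgraph(best)))


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smallest id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
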