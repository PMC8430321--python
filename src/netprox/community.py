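"""Community detection on drug∪disease subnetworks by modularity maximization.

The partition quality is the Newman–Girvan modularity

    Q = sum_c (e_cc - a_c^2)

with e_cc the fraction of edges inside community c and a_c the fraction of
edge endpoints falling in c. Communities are found by greedy agglomerative
modularity maximization (Clauset–Newman–Moore style: repeatedly merge the
pair of communities giving the largest Q increase until no merge improves Q),
the fast-greedy strategy behind the GLay-style clustering used for PPI
subnetworks. Greedy agglomeration is a heuristic: on small graphs it lands at
or very near the exhaustive optimum, but equality is not guaranteed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.community import greedy_modularity_communities


def _as_nx(g) -> nx.Graph:
    return g if isinstance(g, nx.Graph) else g.graph


@dataclass(frozen=True)
class CommunityPartition:
    """A full node partition with its modularity and a reporting threshold.

    Every node is assigned exactly once; indices are contiguous from 0,
    ordered by decreasing community size (ties by smallest member id).
    Communities smaller than ``min_size`` are kept in the assignment but
    listed in ``unclustered`` — they carry no enrichment signal.
    """

    assignment: dict[str, int]
    modularity: float
    min_size: int
    communities: list[list[str]] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def clustered_communities(self) -> list[list[str]]:
        return [c for c in self.communities if len(c) >= self.min_size]


def modularity(g, assignment: Mapping[str, int]) -> float:
    """Newman–Girvan modularity of a full assignment; 0 edges → 0 by convention."""
    graph = _as_nx(g)
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"{len(missing)} node(s) missing from assignment")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    internal: dict[int, int] = {}
    endpoints: dict[int, int] = {}
    for u, v in graph.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            internal[cu] = internal.get(cu, 0) + 1
        endpoints[cu] = endpoints.get(cu, 0) + 1
        endpoints[cv] = endpoints.get(cv, 0) + 1
    q = 0.0
    for c in set(assignment.values()):
        e_cc = internal.get(c, 0) / m
        a_c = endpoints.get(c, 0) / (2 * m)
        q += e_cc - a_c * a_c
    return q


def detect_communities(g, min_size: int = 3) -> CommunityPartition:
    """Partition ``g`` by greedy modularity agglomeration.

    Deterministic for a fixed input: the graph is rebuilt in sorted node/edge
    order before clustering. An edgeless graph yields all-singleton
    communities (every node unclustered for the usual min_size).
    """
    graph = _as_nx(g)
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    h = nx.Graph()
    h.add_nodes_from(sorted(graph.nodes))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges))
    if h.number_of_edges() == 0:
        raw = [{n} for n in sorted(h.nodes)]
    else:
        raw = [set(c) for c in greedy_modularity_communities(h)]
    communities = sorted(
        (sorted(c) for c in raw), key=lambda c: (-len(c), c[0])
    )
    assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    q = modularity(h, assignment)
    unclustered = sorted(
        node for comm in communities if len(comm) < min_size for node in comm
    )
    return CommunityPartition(
        assignment=assignment,
        modularity=q,
        min_size=min_size,
        communities=[list(c) for c in communities],
        unclustered=unclustered,
    )
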