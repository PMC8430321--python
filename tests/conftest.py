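"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: BFS is a
hand-rolled deque traversal (the package uses scipy/networkx), all-pairs
distances use Floyd–Warshall dynamic programming, and modularity optima come
from exhaustive partition enumeration.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from netprox import Interactome, generate_interactome


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def path_graph():
    return Interactome.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def triangle():
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def ba_graph_2000():
    """The standard null-calibration graph: 2,000-node preferential attachment."""
    return generate_interactome(2000, 5, rng_seed=7)


def random_connected_graph(n: int, p: float, seed: int) -> Interactome:
    g = nx.gnp_random_graph(n, p, seed=seed)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    return Interactome(nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes}))


# -- oracles ---------------------------------------------------------------

def bfs_oracle(g: Interactome, sources) -> dict[str, int]:
    """Plain deque BFS from a source set; independent of the package's paths."""
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closest_distance_oracle(g: Interactome, V, T):
    """Brute-force double loop over per-target BFS rows."""
    v_in = set(V) & g.nodes
    t_in = set(T) & g.nodes
    vals, dropped = [], 0
    for t in sorted(t_in):
        row = bfs_oracle(g, [t])
        ds = [row[v] for v in v_in if v in row]
        if ds:
            vals.append(min(ds))
        else:
            dropped += 1
    return (sum(vals) / len(vals) if vals else float("nan")), dropped


def floyd_warshall_oracle(g: Interactome) -> tuple[list[str], np.ndarray]:
    """All-pairs hop distances by dynamic programming."""
    order = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return order, d


def _partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_modularity_exhaustive(g: Interactome) -> float:
    """Exhaustive modularity optimum over every partition (tiny graphs only)."""
    nodes = sorted(g.nodes)
    edges = [tuple(sorted(e)) for e in g.edges()]
    m = len(edges)
    if m == 0:
        return 0.0
    best = -np.inf
    for part in _partitions(nodes):
        comm = {n: i for i, block in enumerate(part) for n in block}
        internal = sum(1 for u, v in edges if comm[u] == comm[v]) / m
        a2 = 0.0
        deg = {n: 0 for n in nodes}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        for block in part:
            a = sum(deg[n] for n in block) / (2 * m)
            a2 += a * a
        best = max(best, internal - a2)
    return best


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration over all C(N, n) draws (tiny N)."""
    universe = range(N)
    special = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_exact(N: int, K: int, n: int, k: int):
    """P(X >= k) as an exact rational from binomial coefficients."""
    from fractions import Fraction
    from math import comb

    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, 0), min(K, n) + 1))
    return Fraction(hits, total)
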