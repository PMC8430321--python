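"""Drug–disease network proximity: closest distance d_c and its Z-score.

For a disease gene set V and a drug target set T on an interactome, the
closest-distance proximity is

    d_c(V, T) = (1 / |T|) * sum_{t in T} min_{v in V} d(v, t)

with d(v, t) the unweighted shortest-path (hop) length. The observed d_c is
standardized against a null of random gene-set pairs matched to V and T in
both size and degree:

    Z_dc = (d_c - mu) / sigma

where mu and sigma are the mean and population standard deviation of d_c over
the random replicates. A strongly negative Z means the drug's targets sit
unusually close to the disease module, beyond what their degrees alone would
produce.

Degree matching uses degree bins grown from the lowest degree upward until
each bin reaches a minimum occupancy (100 nodes for graphs with >= 200 nodes,
max(10, n/10) below that); the final bin absorbs the remainder. Replicate
sets are drawn uniformly without replacement within each bin so their degree
histogram over the bins matches the reference set exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .errors import DegenerateNullError, SamplingError
from .genesets import GeneSet, as_members
from .interactome import Interactome


@dataclass(frozen=True)
class ProximityResult:
    """Observed proximity with its randomized-null calibration."""

    d_c: float
    mu: float
    sigma: float
    z: float
    n_random: int
    n_dropped_targets: int
    rng_seed: int | None

    def to_dict(self) -> dict:
        return {
            "d_c": self.d_c,
            "mu": self.mu,
            "sigma": self.sigma,
            "z": self.z,
            "n_random": self.n_random,
            "n_dropped_targets": self.n_dropped_targets,
            "rng_seed": self.rng_seed,
        }


def _min_distances_from(adj, source_idx: np.ndarray) -> np.ndarray:
    """Min hop distance from any source to every node (multi-source BFS)."""
    return dijkstra(
        adj, directed=False, indices=source_idx, unweighted=True, min_only=True
    )


def _closest_distance_idx(adj, v_idx: np.ndarray, t_idx: np.ndarray):
    dist = _min_distances_from(adj, v_idx)
    d_t = dist[t_idx]
    reachable = np.isfinite(d_t)
    n_dropped = int((~reachable).sum())
    if not reachable.any():
        return np.nan, n_dropped
    return float(d_t[reachable].mean()), n_dropped


def _retained_indices(g: Interactome, genes, label: str) -> np.ndarray:
    members = as_members(genes)
    _, index, _ = g.csr()
    present = sorted(members & g.nodes)
    absent = members - g.nodes
    if absent:
        warnings.warn(
            f"{len(absent)} {label} member(s) absent from the graph were dropped",
            stacklevel=3,
        )
    if not present:
        raise ValueError(f"no {label} member is present in the graph")
    return np.fromiter((index[n] for n in present), dtype=np.intp, count=len(present))


def closest_distance(
    g: Interactome, V: GeneSet, T: GeneSet
) -> tuple[float, int]:
    """d_c(V, T) over the members present in ``g``.

    Targets with no path to any retained V member are excluded from the mean
    and counted in the returned drop count, keeping d_c finite and auditable.
    """
    _, _, adj = g.csr()
    v_idx = _retained_indices(g, V, "disease-set")
    t_idx = _retained_indices(g, T, "target-set")
    return _closest_distance_idx(adj, v_idx, t_idx)


class DegreeBins:
    """Degree bins over a graph's nodes, for degree-matched random sampling."""

    def __init__(self, g: Interactome, min_occupancy: int | None = None):
        order, index, _ = g.csr()
        n = len(order)
        if min_occupancy is None:
            min_occupancy = 100 if n >= 200 else max(10, n // 10)
        degrees = np.array([g.degree(node) for node in order])
        by_degree = np.argsort(degrees, kind="stable")
        bins: list[np.ndarray] = []
        start = 0
        while start < n:
            end = min(start + min_occupancy, n)
            # widen so the bin never splits a degree value
            while end < n and degrees[by_degree[end]] == degrees[by_degree[end - 1]]:
                end += 1
            bins.append(np.sort(by_degree[start:end]))
            start = end
        if len(bins) > 1 and len(bins[-1]) < min_occupancy:
            bins[-2] = np.sort(np.concatenate([bins[-2], bins[-1]]))
            bins.pop()
        self.bins = bins
        self._bin_of = np.empty(n, dtype=np.intp)
        for b, members in enumerate(bins):
            self._bin_of[members] = b
        self._index = index
        self._order = order

    def bin_of_index(self, node_idx: int) -> int:
        return int(self._bin_of[node_idx])

    def bin_counts(self, node_idx: np.ndarray) -> np.ndarray:
        return np.bincount(self._bin_of[node_idx], minlength=len(self.bins))

    def sample_like_idx(
        self,
        reference_idx: np.ndarray,
        rng: np.random.Generator,
        exclude_idx: np.ndarray | None = None,
    ) -> np.ndarray:
        """Sample |reference| distinct node indices matching its bin histogram.

        ``exclude_idx`` removes nodes from the candidate pools (used to keep a
        null (V_rand, T_rand) pair disjoint when the observed pair is).
        """
        counts = self.bin_counts(reference_idx)
        excluded = set() if exclude_idx is None else set(int(i) for i in exclude_idx)
        picks = []
        for b, need in enumerate(counts):
            if need == 0:
                continue
            pool = self.bins[b]
            if excluded:
                pool = pool[~np.isin(pool, list(excluded))]
            if need > len(pool):
                raise SamplingError(
                    f"degree bin {b} holds {len(pool)} candidates but {need} are needed"
                )
            picks.append(rng.choice(pool, size=int(need), replace=False))
        return np.concatenate(picks) if picks else np.empty(0, dtype=np.intp)


def degree_matched_sample(
    g: Interactome, reference: GeneSet, rng: np.random.Generator
) -> GeneSet:
    """A random node set matching ``reference`` in size and degree profile."""
    members = as_members(reference)
    if not members <= g.nodes:
        raise ValueError("reference set must be a subset of the graph's nodes")
    order, index, _ = g.csr()
    ref_idx = np.fromiter((index[n] for n in sorted(members)), dtype=np.intp)
    bins = DegreeBins(g)
    sample_idx = bins.sample_like_idx(ref_idx, rng)
    label = reference.label if isinstance(reference, GeneSet) else "sample"
    return GeneSet.from_iterable(f"{label}_rand", (order[i] for i in sample_idx))


def proximity_z(
    g: Interactome,
    V: GeneSet,
    T: GeneSet,
    n_random: int = 1000,
    rng_seed: int | None = None,
) -> ProximityResult:
    """Observed d_c(V, T) and its Z-score against a degree-matched null.

    Each replicate independently redraws both sets — V_rand matched to V and
    T_rand matched to T — and recomputes d_c. ``sigma`` is the population
    standard deviation over replicates; a zero sigma (all replicates
    identical, e.g. on a complete graph) raises DegenerateNullError rather
    than emitting an undefined Z.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    _, _, adj = g.csr()
    v_idx = _retained_indices(g, V, "disease-set")
    t_idx = _retained_indices(g, T, "target-set")
    d_c, n_dropped = _closest_distance_idx(adj, v_idx, t_idx)

    rng = np.random.default_rng(rng_seed)
    bins = DegreeBins(g)
    # a disjoint observed pair gets disjoint null pairs, so the null mirrors
    # the observed overlap structure (a shared node would force d = 0)
    disjoint = not (set(v_idx.tolist()) & set(t_idx.tolist()))
    null = np.empty(n_random)
    for i in range(n_random):
        v_rand = bins.sample_like_idx(v_idx, rng)
        t_rand = bins.sample_like_idx(
            t_idx, rng, exclude_idx=v_rand if disjoint else None
        )
        null[i], _ = _closest_distance_idx(adj, v_rand, t_rand)
    null = null[np.isfinite(null)]
    mu = float(null.mean())
    sigma = float(null.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateNullError(d_c=d_c, mu=mu)
    z = (d_c - mu) / sigma
    return ProximityResult(
        d_c=d_c,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        n_dropped_targets=n_dropped,
        rng_seed=rng_seed,
    )
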