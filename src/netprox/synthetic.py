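"""Synthetic fixtures with recorded ground truth for every pipeline stage.

Real interactome snapshots, curated disease-gene lists, herbal-compound ADME
tables and annotation collections are all database exports that cannot be
redistributed here; these generators emulate their statistical structure at
desk scale instead. Gene identifiers are synthetic ("G0001"-style) so the
fixtures can never be mistaken for real database content. Every generator is
deterministic given its seed, and every planted quantity (pass counts,
proximity level, planted hub, planted term) is recorded so the corresponding
pipeline module can be checked against construction-time truth.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .errors import GenerationError
from .genesets import GeneSet
from .interactome import Interactome
from .screen import CompoundRecord
from .enrichment import TermCollection


@dataclass(frozen=True)
class SyntheticScenario:
    """A planted drug/disease pair on a synthetic interactome.

    ``proximity_level`` q is the fraction of targets drawn from the disease
    module's immediate (hop <= 1) neighborhood; q=1 plants maximal topological
    proximity, q=0 plants none beyond chance.
    """

    graph: Interactome
    disease_set: GeneSet
    target_set: GeneSet
    proximity_level: float
    rng_seed: int | None
    planted_hub: str | None = None
    ground_truth: dict[str, Any] = field(default_factory=dict)


def generate_interactome(n: int, attach_m: int, rng_seed: int | None = None) -> Interactome:
    """Connected preferential-attachment graph with heavy-tailed degrees.

    Emulates the degree structure of genome-scale interactomes (order
    10^4 nodes, hub-dominated) at a tractable size. Has exactly
    (n - attach_m) * attach_m edges. Node ids are zero-padded "G"-prefixed
    strings.
    """
    if attach_m < 1 or n <= attach_m:
        raise ValueError(f"need n > attach_m >= 1, got n={n}, attach_m={attach_m}")
    g = nx.barabasi_albert_graph(n, attach_m, seed=rng_seed)
    width = max(4, len(str(n - 1)))
    mapping = {i: f"G{i:0{width}d}" for i in g.nodes}
    return Interactome(nx.relabel_nodes(g, mapping))


def _bfs_ball(g: Interactome, start: str, size: int, rng: np.random.Generator) -> list[str]:
    """A connected node set grown by randomized BFS from ``start``."""
    visited = [start]
    seen = {start}
    frontier = [start]
    while len(visited) < size and frontier:
        nxt: list[str] = []
        for node in frontier:
            for nb in sorted(g.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        rng.shuffle(nxt)
        for nb in nxt:
            if len(visited) >= size:
                break
            visited.append(nb)
        frontier = nxt
    return visited


def plant_pair(
    g: Interactome,
    disease_size: int,
    target_size: int,
    q: float,
    rng: np.random.Generator,
    plant_hub: bool = False,
) -> SyntheticScenario:
    """Plant a disease module V and a target set T with proximity level q.

    V is a connected neighborhood (randomized BFS ball). ceil(q * |T|)
    targets are drawn from the nodes at hop exactly 1 from V; the remainder
    is drawn uniformly from outside V's closed neighborhood. T is disjoint
    from V by construction. With ``plant_hub`` the scenario also names the
    target adjacent to the most disease genes (useful as an expected
    top-ranking gene).
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    nodes = sorted(g.nodes)
    if disease_size + target_size > len(nodes):
        raise GenerationError("graph too small for requested set sizes")
    start = nodes[rng.integers(len(nodes))]
    disease = _bfs_ball(g, start, disease_size, rng)
    if len(disease) < disease_size:
        raise GenerationError("disease component too small for requested module size")
    v_set = set(disease)
    ring = sorted({nb for v in v_set for nb in g.neighbors(v)} - v_set)
    outside = sorted(set(nodes) - v_set - set(ring))

    n_near = math.ceil(q * target_size)
    n_far = target_size - n_near
    if n_near > len(ring):
        raise GenerationError(
            f"need {n_near} hop-1 neighbors but only {len(ring)} exist"
        )
    if n_far > len(outside):
        raise GenerationError("not enough nodes outside the closed neighborhood")
    near = list(rng.choice(ring, size=n_near, replace=False)) if n_near else []
    far = list(rng.choice(outside, size=n_far, replace=False)) if n_far else []
    targets = near + far

    hub = None
    if plant_hub and targets:
        hub = max(targets, key=lambda t: (len(g.neighbors(t) & v_set), t))

    seed_val = None  # the caller owns the Generator; record its state source if known
    return SyntheticScenario(
        graph=g,
        disease_set=GeneSet.from_iterable("disease", disease),
        target_set=GeneSet.from_iterable("targets", targets),
        proximity_level=q,
        rng_seed=seed_val,
        planted_hub=hub,
        ground_truth={
            "disease_size": disease_size,
            "target_size": target_size,
            "q": q,
            "n_near": n_near,
            "n_far": n_far,
            "near_targets": sorted(near),
            "far_targets": sorted(far),
        },
    )


def generate_compound_table(
    n_compounds: int,
    herbs: Sequence[str],
    pass_fraction: float,
    rng: np.random.Generator,
    target_pool_size: int = 60,
) -> tuple[list[CompoundRecord], list[tuple[str, str]], dict[str, Any]]:
    """An ADME table with an exact planted pass count, plus target pairs.

    Exactly round(pass_fraction * n_compounds) compounds satisfy both the
    OB >= 30% and DL >= 0.18 cut-offs; the first passing compound sits exactly
    on the boundary (OB = 30.0, DL = 0.18) to pin the inclusive comparison.
    Failures miss at least one criterion. Each compound belongs to 1–2 herbs
    and hits 1–30 targets from a synthetic pool. Ground truth records the
    pass list and the per-herb compound/target tallies.
    """
    if not 0 <= pass_fraction <= 1:
        raise ValueError("pass_fraction must be in [0, 1]")
    if not herbs:
        raise ValueError("need at least one herb label")
    n_pass = round(pass_fraction * n_compounds)
    status = np.zeros(n_compounds, dtype=bool)
    status[:n_pass] = True
    rng.shuffle(status)
    pool = [f"T{i:04d}" for i in range(target_pool_size)]

    records: list[CompoundRecord] = []
    pairs: list[tuple[str, str]] = []
    pass_ids: list[str] = []
    first_pass = True
    for i in range(n_compounds):
        mol_id = f"MOL{i:04d}"
        if status[i]:
            if first_pass:
                ob, dl = 30.0, 0.18  # boundary record, must be retained
                first_pass = False
            else:
                ob = float(rng.uniform(30.0, 100.0))
                dl = float(rng.uniform(0.18, 1.0))
            pass_ids.append(mol_id)
        else:
            mode = rng.integers(3)  # fail OB, fail DL, or fail both
            ob = float(rng.uniform(0.0, 29.9)) if mode in (0, 2) else float(rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.0, 0.17)) if mode in (1, 2) else float(rng.uniform(0.18, 1.0))
        n_herbs = int(rng.integers(1, min(2, len(herbs)) + 1))
        my_herbs = list(rng.choice(list(herbs), size=n_herbs, replace=False))
        for herb in sorted(my_herbs):
            records.append(CompoundRecord(mol_id, f"compound-{i}", herb, ob, dl))
        n_targets = int(rng.integers(1, 31))
        for t in rng.choice(pool, size=min(n_targets, len(pool)), replace=False):
            pairs.append((mol_id, str(t)))

    herbs_of = {}
    targets_of = {}
    for r in records:
        herbs_of.setdefault(r.mol_id, set()).add(r.herb)
    for mol_id, t in pairs:
        targets_of.setdefault(mol_id, set()).add(t)
    truth = {
        "n_pass": n_pass,
        "pass_ids": sorted(pass_ids),
        "per_herb_compounds": {
            h: sum(1 for hs in herbs_of.values() if h in hs) for h in herbs
        },
        "per_herb_targets": {
            h: len(
                set().union(
                    *(targets_of.get(m, set()) for m, hs in herbs_of.items() if h in hs)
                )
                if any(h in hs for hs in herbs_of.values())
                else set()
            )
            for h in herbs
        },
        "all_targets": sorted({t for _, t in pairs}),
    }
    return records, pairs, truth


def generate_term_collection(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_query: Sequence[str] | None,
    planted_overlap: int,
    rng: np.random.Generator,
) -> tuple[TermCollection, dict[str, Any]]:
    """Random flat terms plus (optionally) one planted enriched term.

    The planted term shares exactly ``planted_overlap`` genes with
    ``planted_query``; its remaining members come from outside the query.
    Ground truth names the planted term.
    """
    universe = sorted(set(universe))
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"bad term_size_range {term_size_range} for universe of {len(universe)}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(str(x) for x in rng.choice(universe, size=size, replace=False))
        terms[f"TERM{i:04d}"] = (f"random term {i}", members)

    truth: dict[str, Any] = {"planted_term": None, "planted_overlap": 0}
    if planted_query is not None:
        query = sorted(set(planted_query) & set(universe))
        if planted_overlap > min(hi, len(query)):
            raise GenerationError(
                f"overlap {planted_overlap} infeasible for term sizes <= {hi} "
                f"and query size {len(query)}"
            )
        size = int(rng.integers(max(lo, planted_overlap), hi + 1))
        non_query = sorted(set(universe) - set(query))
        if size - planted_overlap > len(non_query):
            raise GenerationError("universe too small outside the query")
        inside = rng.choice(query, size=planted_overlap, replace=False)
        rest = rng.choice(non_query, size=size - planted_overlap, replace=False)
        members = frozenset(str(x) for x in list(inside) + list(rest))
        term_id = "TERM_PLANTED"
        terms[term_id] = ("planted enriched term", members)
        truth = {"planted_term": term_id, "planted_overlap": planted_overlap,
                 "planted_size": size}
    return TermCollection(terms=terms, universe=frozenset(universe)), truth
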