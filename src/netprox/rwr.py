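"""Random walk with restart (RWR) over an interactome.

The walk iterates

    p_{t+1} = (1 - r) * M @ p_t + r * p_0

where M is the column-stochastic transition matrix (M[i, j] =
A[i, j] / degree(j)), p_0 is uniform over the seed genes and zero elsewhere,
and r is the restart probability (0.75 by default, the convention for
gene-prioritization walks on monoplex PPI networks). Iteration stops when the
L1 change between successive vectors falls below the tolerance (1e-10 by
default). The stationary vector scores every node's affinity to the seed set;
the highest-scoring genes are the candidate hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .genesets import GeneSet, as_members
from .interactome import Interactome


@dataclass(frozen=True)
class TransitionModel:
    """Column-stochastic walk matrix over a fixed node ordering.

    Isolated (degree-0) nodes get an all-zero column and are flagged; a walk
    touching them loses mass except through the restart term.
    """

    nodes: list[str]
    index: dict[str, int]
    M: sp.csr_matrix
    isolated: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class RWRResult:
    scores: dict[str, float]
    seeds: GeneSet
    r: float
    tol: float
    iterations: int
    converged: bool


def build_transition(g: Interactome) -> TransitionModel:
    """Degree-normalized, column-stochastic transition matrix for ``g``."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    order, index, adj = g.csr()
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.zeros_like(degrees)
    nonzero = degrees > 0
    inv[nonzero] = 1.0 / degrees[nonzero]
    M = (adj @ sp.diags(inv)).tocsr()
    isolated = frozenset(order[i] for i in np.flatnonzero(~nonzero))
    return TransitionModel(nodes=order, index=index, M=M, isolated=isolated)


def rwr(
    model: TransitionModel,
    seeds: GeneSet,
    r: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RWRResult:
    """Iterate the restart walk from a seed set to its stationary affinities.

    p_0 is uniform over the seeds present in the graph; seeds absent from the
    graph are dropped with a warning. Non-convergence within ``max_iter``
    returns a result flagged ``converged=False`` with a warning rather than
    raising.
    """
    if not 0 < r <= 1:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    members = as_members(seeds)
    present = sorted(members & set(model.index))
    if not present:
        raise ValueError("no seed is present in the graph")
    if len(present) < len(members):
        warnings.warn(
            f"{len(members) - len(present)} seed(s) absent from the graph were dropped",
            stacklevel=2,
        )
    n = len(model.nodes)
    p0 = np.zeros(n)
    p0[[model.index[s] for s in present]] = 1.0 / len(present)

    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = (1.0 - r) * (model.M @ p) + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RWR did not converge within {max_iter} iterations (L1 change {delta:g})",
            stacklevel=2,
        )
    seed_set = seeds if isinstance(seeds, GeneSet) else GeneSet.from_iterable("seeds", members)
    scores = {node: float(p[i]) for i, node in enumerate(model.nodes)}
    return RWRResult(
        scores=scores,
        seeds=seed_set,
        r=r,
        tol=tol,
        iterations=iterations,
        converged=converged,
    )


def rwr_linear_solve(model: TransitionModel, seeds: GeneSet, r: float = 0.75) -> np.ndarray:
    """Closed-form stationary vector p = r (I - (1-r) M)^-1 p_0.

    Direct dense solve; intended as an independent cross-check of the
    iterative walk on small graphs.
    """
    members = sorted(as_members(seeds) & set(model.index))
    if not members:
        raise ValueError("no seed is present in the graph")
    n = len(model.nodes)
    p0 = np.zeros(n)
    p0[[model.index[s] for s in members]] = 1.0 / len(members)
    A = np.eye(n) - (1.0 - r) * model.M.toarray()
    return r * np.linalg.solve(A, p0)


def rank_top(
    result: RWRResult, k: int, exclude_seeds: bool = False
) -> list[tuple[str, float]]:
    """Top-k nodes by descending affinity; ties broken by ascending node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = result.scores.items()
    if exclude_seeds:
        items = (it for it in items if it[0] not in result.seeds.members)
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
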