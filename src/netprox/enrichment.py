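"""Hypergeometric over-representation analysis against GMT term collections.

For a query of n genes (after intersecting with the collection's universe of
N genes) and a term of K genes sharing k with the query, the enrichment
p-value is the upper hypergeometric tail P(X >= k) with
X ~ Hypergeometric(N, K, n). Multiple testing is controlled with
Benjamini–Hochberg by default; a raw-p mode reproduces the uncorrected
p < alpha cut common in network-pharmacology reports. No ontology structure
is used: terms are flat gene sets, as supplied.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, as_members

_CORRECTIONS = ("benjamini_hochberg", "none")


@dataclass(frozen=True)
class TermCollection:
    """Named gene-set terms over a declared gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self):
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"term {term_id!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset[str]
    a_only: int
    b_only: int
    both: int


def overlap(a: GeneSet | Iterable[str], b: GeneSet | Iterable[str]) -> OverlapResult:
    """Exact intersection of two gene sets with the Venn-diagram counts."""
    sa, sb = as_members(a), as_members(b)
    shared = sa & sb
    return OverlapResult(
        shared=shared, a_only=len(sa - sb), b_only=len(sb - sa), both=len(shared)
    )


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> TermCollection:
    """Read a GMT file (term_id <tab> term_name <tab> gene1 <tab> gene2 ...).

    When no universe is supplied, the union of all term members is used.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs >= 3 tab-separated fields: {line!r}")
            term_id, name = parts[0], parts[1]
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            terms[term_id] = (name, genes)
    if universe is None:
        uni = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
    else:
        uni = frozenset(universe)
    return TermCollection(terms=terms, universe=uni)


def write_gmt(collection: TermCollection, path: str | Path) -> None:
    lines = []
    for term_id in sorted(collection.terms):
        name, members = collection.terms[term_id]
        lines.append("\t".join([term_id, name, *sorted(members)]) + "\n")
    Path(path).write_text("".join(lines))


def enrich(
    query: GeneSet | Iterable[str],
    collection: TermCollection,
    alpha: float = 0.05,
    correction: str = "benjamini_hochberg",
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in every term.

    Query genes outside the universe are dropped with a warning (n counts the
    retained genes only). Rows come back sorted by ascending p, ties by term
    id; significance is judged on the corrected p (or raw p when
    ``correction="none"``).
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {_CORRECTIONS}")
    members = as_members(query)
    retained = members & collection.universe
    if not retained:
        raise ValueError("query has no genes in the collection's universe")
    if len(retained) < len(members):
        warnings.warn(
            f"{len(members) - len(retained)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    N, n = len(collection.universe), len(retained)
    term_ids = sorted(collection.terms)
    ks, Ks = [], []
    for term_id in term_ids:
        _, term_members = collection.terms[term_id]
        ks.append(len(term_members & retained))
        Ks.append(len(term_members))
    ks_arr = np.array(ks)
    Ks_arr = np.array(Ks)
    # P(X >= k) == survival function at k-1
    pvals = hypergeom.sf(ks_arr - 1, N, Ks_arr, n)
    pvals = np.clip(pvals, 0.0, 1.0)
    if correction == "benjamini_hochberg":
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        p_adj = np.maximum(p_adj, pvals)
    else:
        p_adj = pvals
    rows = [
        EnrichmentRow(
            term_id=tid,
            term_name=collection.terms[tid][0],
            k=int(k),
            K=int(K),
            n=n,
            N=N,
            p=float(p),
            p_adj=float(pa),
            significant=bool(pa < alpha),
        )
        for tid, k, K, p, pa in zip(term_ids, ks_arr, Ks_arr, pvals, p_adj)
    ]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def overlapped_terms(
    rows_a: list[EnrichmentRow],
    rows_b: list[EnrichmentRow],
    alpha: float = 0.05,
) -> set[str]:
    """Term ids significant (adjusted p < alpha) in both enrichment results.

    Both inputs must come from the same collection; a mismatch in the
    (term, term size, universe size) fingerprint is an error.
    """
    fp_a = {(r.term_id, r.K, r.N) for r in rows_a}
    fp_b = {(r.term_id, r.K, r.N) for r in rows_b}
    if fp_a != fp_b:
        raise ValueError("enrichment results come from different collections")
    sig_a = {r.term_id for r in rows_a if r.p_adj < alpha}
    sig_b = {r.term_id for r in rows_b if r.p_adj < alpha}
    return sig_a & sig_b
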