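"""Hypergeometric over-representation, BH correction, term overlap."""

from fractions import Fraction

import numpy as np
import pytest

from netprox import (
    GeneSet,
    TermCollection,
    enrich,
    generate_term_collection,
    overlap,
    overlapped_terms,
    read_gmt,
    write_gmt,
)

from conftest import hypergeom_tail_enumeration, hypergeom_tail_exact


def gs(label, members):
    return GeneSet.from_iterable(label, members)


UNIVERSE = [f"g{i:03d}" for i in range(10)]


def make_collection(term_members: dict, universe=None):
    return TermCollection(
        terms={tid: (tid.lower(), frozenset(members)) for tid, members in term_members.items()},
        universe=frozenset(universe or UNIVERSE),
    )


class TestOverlap:
    def test_hand_set_algebra(self):
        res = overlap(gs("a", ["X", "Y"]), gs("b", ["Y", "Z"]))
        assert res.shared == {"Y"}
        assert (res.a_only, res.b_only, res.both) == (1, 1, 1)

    def test_disjoint(self):
        assert overlap(gs("a", "AB"), gs("b", "CD")).shared == frozenset()

    def test_random_sets_match_sorted_merge_oracle(self, rng):
        pool = [f"g{i}" for i in range(300)]
        a = set(rng.choice(pool, 100, replace=False))
        b = set(rng.choice(pool, 80, replace=False))
        # independent oracle: count via sorted-merge walk
        sa, sb = sorted(a), sorted(b)
        i = j = both = 0
        while i < len(sa) and j < len(sb):
            if sa[i] == sb[j]:
                both += 1; i += 1; j += 1
            elif sa[i] < sb[j]:
                i += 1
            else:
                j += 1
        res = overlap(gs("a", a), gs("b", b))
        assert res.both == both
        assert res.a_only == len(a) - both and res.b_only == len(b) - both


class TestEnrich:
    def test_disjoint_term_has_p_one(self):
        coll = make_collection({"T1": UNIVERSE[:5]})
        rows = enrich(gs("q", UNIVERSE[5:]), coll)
        assert rows[0].k == 0 and rows[0].p == pytest.approx(1.0)

    def test_perfect_overlap_exact_value(self):
        # N=10, K=5, n=5, k=5 → 1 / C(10,5) = 1/252
        coll = make_collection({"T1": UNIVERSE[:5]})
        rows = enrich(gs("q", UNIVERSE[:5]), coll)
        assert rows[0].p == pytest.approx(1 / 252, rel=1e-12)

    def test_tail_matches_exhaustive_enumeration(self):
        # enumeration over all C(N, n) draws for a handful of small configs
        for N, K, n in [(8, 3, 4), (10, 5, 5), (9, 4, 3)]:
            universe = [f"u{i}" for i in range(N)]
            term = universe[:K]
            query = universe[: n]  # overlap k = min(K, n)
            coll = make_collection({"T": term}, universe)
            row = enrich(gs("q", query), coll)[0]
            want = hypergeom_tail_enumeration(N, K, n, row.k)
            assert row.p == pytest.approx(want, abs=1e-12)

    def test_combinatorial_formula_agrees_with_enumeration(self):
        # ties the closed-form oracle used elsewhere back to raw enumeration
        for N, K, n, k in [(8, 3, 4, 2), (10, 5, 5, 3), (9, 4, 3, 1)]:
            assert float(hypergeom_tail_exact(N, K, n, k)) == pytest.approx(
                hypergeom_tail_enumeration(N, K, n, k), abs=1e-12
            )

    def test_bh_monotone_and_above_raw_p(self, rng):
        universe = [f"g{i}" for i in range(200)]
        coll, _ = generate_term_collection(
            universe, 30, (10, 40), planted_query=None, planted_overlap=0, rng=rng
        )
        query = gs("q", rng.choice(universe, 40, replace=False))
        rows = enrich(query, coll)
        adj = [r.p_adj for r in rows]
        assert all(r.p_adj >= r.p for r in rows)
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_rows_sorted_by_p(self, rng):
        universe = [f"g{i}" for i in range(100)]
        coll, _ = generate_term_collection(universe, 20, (5, 30), None, 0, rng)
        rows = enrich(gs("q", universe[:25]), coll)
        assert [r.p for r in rows] == sorted(r.p for r in rows)

    def test_query_outside_universe_dropped_with_warning(self):
        coll = make_collection({"T1": UNIVERSE[:5]})
        with pytest.warns(UserWarning):
            rows = enrich(gs("q", UNIVERSE[:3] + ["alien"]), coll)
        assert rows[0].n == 3

    def test_empty_query_universe_intersection_rejected(self):
        coll = make_collection({"T1": UNIVERSE[:5]})
        with pytest.raises(ValueError):
            enrich(gs("q", ["alien"]), coll)

    def test_raw_p_mode(self):
        coll = make_collection({"T1": UNIVERSE[:5], "T2": UNIVERSE[2:8]})
        rows = enrich(gs("q", UNIVERSE[:5]), coll, correction="none")
        assert all(r.p_adj == r.p for r in rows)

    def test_planted_term_detected(self, rng):
        universe = [f"g{i:04d}" for i in range(2000)]
        query = list(rng.choice(universe, 150, replace=False))
        coll, truth = generate_term_collection(
            universe, 50, (50, 200), planted_query=query, planted_overlap=30, rng=rng
        )
        rows = enrich(gs("q", query), coll)
        assert rows[0].term_id == truth["planted_term"]
        assert rows[0].significant


class TestOverlappedTerms:
    def _rows(self, rng, query):
        universe = [f"g{i:04d}" for i in range(500)]
        coll, _ = generate_term_collection(universe, 25, (20, 60), None, 0, rng)
        return enrich(gs("q", query), coll), universe

    def test_identical_queries_share_all_significant(self, rng):
        universe = [f"g{i:04d}" for i in range(500)]
        coll, truth = generate_term_collection(
            universe, 25, (20, 60),
            planted_query=universe[:80], planted_overlap=40, rng=rng,
        )
        rows = enrich(gs("q", universe[:80]), coll)
        shared = overlapped_terms(rows, rows)
        assert shared == {r.term_id for r in rows if r.p_adj < 0.05}
        assert truth["planted_term"] in shared

    def test_no_significant_terms_gives_empty(self, rng):
        universe = [f"g{i:04d}" for i in range(500)]
        coll, _ = generate_term_collection(universe, 10, (20, 60), None, 0, rng)
        rows_a = enrich(gs("a", rng.choice(universe, 50, replace=False)), coll)
        rows_b = [r for r in rows_a]
        no_sig = [r for r in rows_a if not r.significant]
        if no_sig:
            assert overlapped_terms(no_sig, no_sig) == set()

    def test_mismatched_collections_rejected(self, rng):
        universe = [f"g{i:04d}" for i in range(500)]
        coll_a, _ = generate_term_collection(universe, 10, (20, 60), None, 0, rng)
        coll_b, _ = generate_term_collection(universe, 12, (20, 60), None, 0, rng)
        q = gs("q", universe[:50])
        with pytest.raises(ValueError):
            overlapped_terms(enrich(q, coll_a), enrich(q, coll_b))

    def test_planted_common_term_recovered(self, rng):
        universe = [f"g{i:04d}" for i in range(2000)]
        qa = list(rng.choice(universe, 120, replace=False))
        qb = list(rng.choice(universe, 120, replace=False))
        common = list(rng.choice(universe, 60, replace=False))
        # both queries share half their genes with one common pool, so the
        # planted term built on that pool is enriched in both
        qa[:30] = common[:30]
        qb[:30] = common[:30]
        terms = {"T_COMMON": ("common", frozenset(common[:40]))}
        for i in range(20):
            members = frozenset(str(x) for x in rng.choice(universe, 50, replace=False))
            terms[f"T{i:02d}"] = (f"t{i}", members)
        coll = TermCollection(terms=terms, universe=frozenset(universe))
        shared = overlapped_terms(enrich(gs("a", qa), coll), enrich(gs("b", qb), coll))
        assert shared == {"T_COMMON"}


class TestGmtIO:
    def test_round_trip_preserves_memberships(self, tmp_path, rng):
        universe = [f"g{i}" for i in range(100)]
        coll, _ = generate_term_collection(universe, 8, (5, 20), universe[:30], 5, rng)
        write_gmt(coll, tmp_path / "terms.gmt")
        back = read_gmt(tmp_path / "terms.gmt", universe=universe)
        assert back.terms == coll.terms

    def test_short_line_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("T1\tonly-name\n")
        with pytest.raises(ValueError):
            read_gmt(tmp_path / "bad.gmt")

    def test_term_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            make_collection({"T1": ["alien"]})
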