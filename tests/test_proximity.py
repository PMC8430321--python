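"""Closest-distance proximity and its degree-matched randomized null."""

import numpy as np
import pytest

from netprox import (
    DegenerateNullError,
    DegreeBins,
    GeneSet,
    Interactome,
    closest_distance,
    degree_matched_sample,
    generate_interactome,
    plant_pair,
    proximity_z,
)

from conftest import closest_distance_oracle, random_connected_graph


def gs(label, members):
    return GeneSet.from_iterable(label, members)


class TestClosestDistance:
    def test_targets_inside_disease_set_give_zero(self, path_graph):
        d, dropped = closest_distance(path_graph, gs("V", "abc"), gs("T", "ab"))
        assert d == 0.0 and dropped == 0

    def test_path_graph_arithmetic(self, path_graph):
        # V={a}, T={d,e} on a-b-c-d-e: (3 + 4) / 2
        d, _ = closest_distance(path_graph, gs("V", ["a"]), gs("T", ["d", "e"]))
        assert d == pytest.approx(3.5)

    def test_unreachable_targets_counted_not_averaged(self):
        g = Interactome.from_edges([("a", "b"), ("x", "y")])
        d, dropped = closest_distance(g, gs("V", ["a"]), gs("T", ["b", "x"]))
        assert d == 1.0 and dropped == 1

    def test_members_absent_from_graph_warned_and_dropped(self, path_graph):
        with pytest.warns(UserWarning):
            d, _ = closest_distance(path_graph, gs("V", ["a", "zz"]), gs("T", ["b"]))
        assert d == 1.0

    def test_empty_intersection_rejected(self, path_graph):
        with pytest.raises(ValueError):
            closest_distance(path_graph, gs("V", ["nope"]), gs("T", ["a"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_double_loop(self, seed):
        g = random_connected_graph(80, 0.05, seed)
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes)
        V = gs("V", rng.choice(nodes, 20, replace=False))
        T = gs("T", rng.choice(nodes, 10, replace=False))
        got, dropped = closest_distance(g, V, T)
        want, want_dropped = closest_distance_oracle(g, V.members, T.members)
        assert got == pytest.approx(want) and dropped == want_dropped

    def test_scale_free_instance_matches_oracle(self, rng):
        g = generate_interactome(200, 3, rng_seed=11)
        nodes = sorted(g.nodes)
        V = gs("V", rng.choice(nodes, 20, replace=False))
        T = gs("T", rng.choice(nodes, 10, replace=False))
        got, _ = closest_distance(g, V, T)
        want, _ = closest_distance_oracle(g, V.members, T.members)
        assert got == pytest.approx(want)


class TestDegreeMatchedSample:
    def test_regular_graph_single_bin(self, rng):
        # a cycle is 2-regular: any k-subset is admissible
        n = 30
        g = Interactome.from_edges([(f"v{i}", f"v{(i + 1) % n}") for i in range(n)])
        ref = gs("ref", [f"v{i}" for i in range(5)])
        sample = degree_matched_sample(g, ref, rng)
        assert len(sample) == 5 and sample.members <= g.nodes
        assert len(DegreeBins(g).bins) == 1

    def test_reference_equal_to_all_nodes_exhausts_graph(self, rng):
        g = random_connected_graph(25, 0.15, 0)
        sample = degree_matched_sample(g, gs("all", g.nodes), rng)
        assert sample.members == g.nodes

    def test_reference_outside_graph_rejected(self, triangle, rng):
        with pytest.raises(ValueError):
            degree_matched_sample(triangle, gs("r", ["A", "Z"]), rng)

    def test_bin_histogram_matches_reference_over_draws(self, rng):
        g = generate_interactome(1000, 4, rng_seed=5)
        # take the 30 highest-degree nodes as a hub-heavy reference
        hubs = sorted(g.nodes, key=lambda n: (-g.degree(n), n))[:30]
        ref = gs("hubs", hubs)
        bins = DegreeBins(g)
        order, index, _ = g.csr()
        ref_idx = np.array([index[n] for n in hubs])
        ref_counts = bins.bin_counts(ref_idx)
        for _ in range(100):
            sample = degree_matched_sample(g, ref, rng)
            s_idx = np.array([index[n] for n in sorted(sample.members)])
            assert np.array_equal(bins.bin_counts(s_idx), ref_counts)

    def test_small_graph_min_occupancy_rule(self):
        g = random_connected_graph(100, 0.06, 1)
        bins = DegreeBins(g)
        # n < 200: minimum occupancy max(10, n/10) = 10, except where a single
        # degree value overflows a bin
        assert all(len(b) >= 10 for b in bins.bins[:-1])


class TestProximityZ:
    def test_complete_graph_null_is_degenerate(self):
        nodes = [f"k{i}" for i in range(8)]
        g = Interactome.from_edges(
            [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
        )
        with pytest.raises(DegenerateNullError) as exc:
            proximity_z(g, gs("V", nodes[:3]), gs("T", nodes[3:6]), n_random=10, rng_seed=0)
        assert exc.value.d_c == 1.0 and exc.value.mu == 1.0

    def test_identical_seed_bit_identical_result(self, ba_graph_2000, rng):
        nodes = sorted(ba_graph_2000.nodes)
        V = gs("V", rng.choice(nodes, 20, replace=False))
        T = gs("T", rng.choice(nodes, 10, replace=False))
        a = proximity_z(ba_graph_2000, V, T, n_random=20, rng_seed=42)
        b = proximity_z(ba_graph_2000, V, T, n_random=20, rng_seed=42)
        assert a == b

    def test_n_random_lower_bound(self, path_graph):
        with pytest.raises(ValueError):
            proximity_z(path_graph, gs("V", ["a"]), gs("T", ["e"]), n_random=1)

    def test_planted_proximal_pair_scores_negative(self):
        g = generate_interactome(500, 4, rng_seed=9)
        rng = np.random.default_rng(17)
        scen = plant_pair(g, 20, 10, q=1.0, rng=rng)
        res = proximity_z(g, scen.disease_set, scen.target_set, n_random=100, rng_seed=3)
        assert res.d_c <= 1.0
        assert res.z < 0

    def test_z_consistent_with_mu_sigma(self, ba_graph_2000, rng):
        nodes = sorted(ba_graph_2000.nodes)
        V = gs("V", rng.choice(nodes, 15, replace=False))
        T = gs("T", rng.choice(nodes, 8, replace=False))
        res = proximity_z(ba_graph_2000, V, T, n_random=30, rng_seed=5)
        assert res.z == pytest.approx((res.d_c - res.mu) / res.sigma)
        assert res.sigma >= 0 and res.n_random == 30
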