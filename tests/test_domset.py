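"""Exact dominating-set computation: oracles, ILP, preprocessing, MDSI."""

import pytest

from conftest import er_graph, random_two_layer
from multidom.domset import (
    brute_force_mds,
    brute_force_mdsm,
    fast_mdsm,
    fast_mdsm_preprocess,
    ilp_mds,
    ilp_mdsm,
    is_dominating,
    mdsi,
    sandwich_bounds,
)
from multidom.generators import gen_k_regular, gen_powerlaw, rewire_degree_preserving
from multidom.netcore import MultilayerNetwork, new_graph


class TestBruteForce:
    def test_star_center(self, star5):
        res = brute_force_mds(star5)
        assert res.size == 1 and res.members == {"x"}

    def test_path4(self, path4):
        assert brute_force_mds(path4).size == 2

    def test_cycle6(self, cycle6):
        assert brute_force_mdsm(MultilayerNetwork([cycle6])).size == 2

    def test_identical_layers_match_single_layer(self, path4):
        net = MultilayerNetwork([path4, path4])
        assert brute_force_mdsm(net).size == brute_force_mds(path4).size

    def test_disjoint_layers_sum(self):
        net = MultilayerNetwork(
            [new_graph("ab", [("a", "b")]), new_graph("cd", [("c", "d")])]
        )
        assert brute_force_mdsm(net).size == 2

    def test_overlapping_edges_share_dominator(self):
        net = MultilayerNetwork(
            [new_graph("ab", [("a", "b")]), new_graph("bc", [("b", "c")])]
        )
        res = brute_force_mdsm(net)
        assert res.size == 1 and res.members == {"b"}

    def test_size_guards(self):
        big = new_graph([f"v{i}" for i in range(30)])
        with pytest.raises(ValueError):
            brute_force_mds(big)
        with pytest.raises(ValueError):
            brute_force_mdsm(MultilayerNetwork([new_graph([f"v{i}" for i in range(21)])]))


class TestIlpMds:
    def test_star(self):
        g = new_graph("cabdefghij", [("c", v) for v in "abdefghij"])
        assert ilp_mds(g).size == 1

    def test_isolated_nodes_variants(self):
        g = new_graph("abc")
        assert ilp_mds(g, include_isolated=True).size == 3
        assert ilp_mds(g, include_isolated=False).size == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        g = er_graph(12, 0.3, seed)
        assert ilp_mds(g).size == brute_force_mds(g).size

    def test_canonical_solution_is_reproducible(self):
        g = er_graph(15, 0.25, 77)
        a = ilp_mds(g, canonical=True)
        b = ilp_mds(g, canonical=True)
        assert a.members == b.members
        assert a.size == ilp_mds(g).size


class TestIlpMdsm:
    def test_single_layer_reduction(self, cycle6):
        assert ilp_mdsm(MultilayerNetwork([cycle6])).size == ilp_mds(cycle6).size

    def test_identical_layers_repeated(self, path4):
        net = MultilayerNetwork([path4] * 4)
        assert ilp_mdsm(net).size == ilp_mds(path4).size

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_two_layers(self, seed):
        net = random_two_layer(10, 0.3, seed)
        assert ilp_mdsm(net).size == brute_force_mdsm(net).size

    def test_forced_nodes_are_respected(self, path4):
        res = ilp_mdsm(MultilayerNetwork([path4]), forced={"a"})
        assert "a" in res.members and res.forced_subset == {"a"}

    def test_forced_outside_universe_rejected(self, path4):
        with pytest.raises(ValueError):
            ilp_mdsm(MultilayerNetwork([path4]), forced={"zz"})

    def test_domination_certificate(self):
        net = random_two_layer(12, 0.25, 5)
        res = ilp_mdsm(net)
        assert is_dominating(net, res.members)


class TestPreprocessing:
    def test_exclusive_leaf_rule(self):
        """A layer-1 leaf absent from layer 2 pins its neighbour."""
        g1 = new_graph("xpq", [("x", "p"), ("x", "q")])
        g2 = new_graph("xy", [("x", "y")])
        state = fast_mdsm_preprocess(MultilayerNetwork([g1, g2]))
        assert state.v_m == {"x"}
        assert {"p", "q"} <= state.observed_1

    def test_shared_leaf_rule_lexicographic(self):
        """Identical single edge in both layers: the scan meets 'a' first,
        finds leaf 'b', and pins 'a'."""
        e = new_graph("ab", [("a", "b")])
        state = fast_mdsm_preprocess(MultilayerNetwork([e, new_graph("ab", [("a", "b")])]))
        assert state.v_m == {"a"}
        assert "b" in state.observed_1 and "b" in state.observed_2

    def test_no_rule_fires_without_degree_one_nodes(self):
        layers = [gen_k_regular(12, 3, s) for s in (0, 1)]
        state = fast_mdsm_preprocess(MultilayerNetwork(layers))
        assert state.v_m == set()

    def test_requires_two_layers(self, path4):
        with pytest.raises(ValueError):
            fast_mdsm_preprocess(MultilayerNetwork([path4]))

    def test_multiplex_inputs_only_fire_shared_rule(self):
        """With identical node sets the single-layer rules never apply."""
        g1 = new_graph("abc", [("a", "b"), ("b", "c")])
        g2 = new_graph("abc", [("a", "b")])
        state = fast_mdsm_preprocess(MultilayerNetwork([g1, g2]))
        # 'c' is a leaf of layer 1 but exists in layer 2, so the exclusive
        # rule cannot fire on it; the shared edge {a,b} (a of degree 1 in
        # both layers) fires the joint rule at the scan step v_i = b
        assert state.v_m == {"b"}
        assert "a" in state.observed_1 and "a" in state.observed_2


class TestFastMdsm:
    @pytest.mark.parametrize("seed", range(10))
    def test_preprocessing_size_equivalence_small(self, seed):
        net = random_two_layer(10, 0.3, 100 + seed)
        assert fast_mdsm(net).size == ilp_mdsm(net).size

    @pytest.mark.parametrize("seed", range(5))
    def test_preprocessing_size_equivalence_scale_free(self, seed):
        g = gen_powerlaw(150, 2.5, seed)
        gk, _ = rewire_degree_preserving(g, 50, 1000 + seed)
        net = MultilayerNetwork([g, gk])
        with_pre = fast_mdsm(net)
        without = fast_mdsm(net, preprocess=False)
        assert with_pre.size == without.size
        assert with_pre.forced_subset <= with_pre.members
        assert is_dominating(net, with_pre.members)

    def test_identical_layers(self, cycle6):
        net = MultilayerNetwork([cycle6, cycle6])
        assert fast_mdsm(net).size == ilp_mds(cycle6).size

    def test_disjoint_node_sets_sum(self):
        g1 = new_graph("ab", [("a", "b")])
        g2 = new_graph("cd", [("c", "d")])
        net = MultilayerNetwork([g1, g2])
        assert fast_mdsm(net).size == ilp_mds(g1).size + ilp_mds(g2).size

    def test_three_layers_delegate_to_plain_ilp(self):
        layers = [er_graph(8, 0.3, s) for s in range(3)]
        net = MultilayerNetwork(layers)
        res = fast_mdsm(net)
        assert res.forced_subset == frozenset()
        assert res.size == brute_force_mdsm(net).size


class TestMdsi:
    def test_identical_layers_equal_mds(self, cycle6):
        res = mdsi(cycle6, cycle6)
        assert res.size == ilp_mds(cycle6).size

    def test_intersection_bound(self):
        for seed in range(5):
            net = random_two_layer(10, 0.35, 200 + seed)
            g1, g2 = net[0], net[1]
            res = mdsi(g1, g2)
            assert res.size <= min(ilp_mds(g1).size, ilp_mds(g2).size)

    def test_constructed_singleton_intersection(self):
        """Per-layer MDSs engineered to share exactly the hub node."""
        g1 = new_graph("abcde", [("c", v) for v in "abde"])
        g2 = new_graph("abcde", [("c", "a"), ("c", "b"), ("d", "e")])
        res = mdsi(g1, g2)
        assert res.members == {"c"}
        # cross-check the engineered layers against the exhaustive oracle
        assert brute_force_mds(g1).size == 1 and brute_force_mds(g2).size == 2


class TestSandwichBounds:
    def test_identical_layers_hit_lower_bound(self, path4):
        net = MultilayerNetwork([path4, path4])
        lower, upper = sandwich_bounds(net)
        assert lower == ilp_mds(path4).size == fast_mdsm(net).size
        assert upper == 2 * lower  # the sum bound stays a sum

    def test_disjoint_layers_hit_upper(self):
        net = MultilayerNetwork(
            [new_graph("ab", [("a", "b")]), new_graph("cd", [("c", "d")])]
        )
        lower, upper = sandwich_bounds(net)
        assert fast_mdsm(net).size == upper

    @pytest.mark.parametrize("seed", range(10))
    def test_bound_chain(self, seed):
        net = random_two_layer(10, 0.3, 300 + seed)
        lower, upper = sandwich_bounds(net)
        size = fast_mdsm(net).size
        assert lower <= size <= upper


class TestSaturationTendency:
    def test_many_distinct_sparse_layers_saturate(self):
        """With enough distinct 2-regular layers on 8 nodes the MDSM size
        reaches n - d_min = 6, and the hit frequency grows with N."""

        def freq(n_layers):
            hits = 0
            for s in range(5):
                layers = [gen_k_regular(8, 2, 5000 * s + i) for i in range(n_layers)]
                hits += ilp_mdsm(MultilayerNetwork(layers)).size >= 6
            return hits / 5

        low, high = freq(4), freq(40)
        assert low <= high
        assert high == 1.0
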