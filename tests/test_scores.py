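import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robcomplex import (
    cluster_node_distance,
    edge_weight,
    neighbour_affinity,
    neighbourhood_graph,
    node_weight,
    robustness,
)
from tests.conftest import labelled
from tests.oracles import naive_cluster_node_distance


class TestEdgeWeight:
    def test_triangle_edge(self, triangle):
        assert edge_weight(triangle, "a", "b") == pytest.approx(1 / 3)

    def test_k4_edge(self, k4):
        assert edge_weight(k4, "n00", "n01") == pytest.approx(0.5)

    def test_star_edge_is_zero(self, star5):
        assert edge_weight(star5, "n00", "n01") == 0.0

    def test_non_edge_raises(self, triangle):
        triangle.add_node("z")
        with pytest.raises(ValueError):
            edge_weight(triangle, "a", "z")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded_on_random_graphs(self, seed):
        g = labelled(nx.gnp_random_graph(10, 0.4, seed=seed))
        for u, v in g.edges:
            w = edge_weight(g, u, v)
            assert 0.0 <= w <= 1.0
            assert w == edge_weight(g, v, u)


class TestNeighbourhoodGraph:
    def test_k4_keeps_everything(self, k4):
        ng = neighbourhood_graph(k4, "n00")
        assert ng.retained_nodes == frozenset(k4.nodes)
        assert len(ng.retained_edges) == 6

    def test_star_centre_prunes_all_leaves(self, star5):
        ng = neighbourhood_graph(star5, "n00")
        assert ng.retained_nodes == frozenset({"n00"})
        assert ng.retained_edges == frozenset()

    def test_pendant_pair_prunes_both(self):
        g = nx.Graph([("v", "u")])
        ng = neighbourhood_graph(g, "v")
        assert ng.retained_nodes == frozenset()

    def test_unknown_node_raises(self, k4):
        with pytest.raises(ValueError):
            neighbourhood_graph(k4, "ghost")


class TestNodeWeight:
    def test_k4(self, k4):
        assert node_weight(k4, "n00") == pytest.approx(3.0)

    def test_star_centre(self, star5):
        assert node_weight(star5, "n00") == 0.0

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("solo")
        assert node_weight(g, "solo") == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_two_e_over_v_of_pruned_graph(self, seed):
        g = labelled(nx.gnp_random_graph(12, 0.3, seed=seed))
        for v in g.nodes:
            ng = neighbourhood_graph(g, v)
            expected = (
                0.0
                if not ng.retained_nodes
                else 2 * len(ng.retained_edges) / len(ng.retained_nodes)
            )
            assert node_weight(g, v) == pytest.approx(expected)


class TestClusterNodeDistance:
    def test_perfect_absorption(self):
        g = nx.Graph([("a", "v")])
        assert cluster_node_distance(g, {"a"}, "v").d == 0.0

    def test_triangle_with_external_edges(self):
        g = nx.Graph(
            [("a", "b"), ("b", "c"), ("c", "a"), ("v", "a"), ("v", "b"), ("v", "x"), ("c", "y")]
        )
        bd = cluster_node_distance(g, {"a", "b", "c"}, "v")
        assert (bd.m, bd.deg_K, bd.deg_v, bd.out_K, bd.out_v) == (2, 3, 3, 1, 1)
        assert bd.d == pytest.approx(1 / 3 + 2 / 5)

    def test_path_cluster_single_attachment(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("v", "a")])
        bd = cluster_node_distance(g, {"a", "b", "c"}, "v")
        assert bd.d == pytest.approx(2 / 3)

    def test_member_candidate_raises(self, triangle):
        with pytest.raises(ValueError):
            cluster_node_distance(triangle, {"a", "b"}, "a")

    def test_empty_cluster_raises(self, triangle):
        with pytest.raises(ValueError):
            cluster_node_distance(triangle, set(), "a")

    def test_matches_enumeration_oracle_on_random_instances(self):
        """Optimized counts agree exactly with brute-force enumeration."""
        import random

        rng = random.Random(20260921)
        checked = 0
        while checked < 1200:
            n = rng.randint(3, 12)
            g = labelled(nx.gnp_random_graph(n, rng.uniform(0.15, 0.8), seed=rng.randrange(2**31)))
            nodes = sorted(g.nodes)
            v = rng.choice(nodes)
            pool = [u for u in nodes if u != v]
            k_size = rng.randint(1, len(pool))
            K = set(rng.sample(pool, k_size))
            m, deg_K, deg_v, out_K, out_v, d = naive_cluster_node_distance(g, K, v)
            bd = cluster_node_distance(g, K, v)
            assert (bd.m, bd.deg_K, bd.deg_v, bd.out_K, bd.out_v) == (
                m,
                deg_K,
                deg_v,
                out_K,
                out_v,
            )
            assert bd.d == d
            checked += 1


class TestRobustness:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_complete_graphs_fully_robust(self, n):
        g = labelled(nx.complete_graph(n))
        res = robustness(g.nodes, g.edges)
        assert res.R == 1.0
        assert res.n_removed == n

    @pytest.mark.parametrize("k", [2, 3, 5, 9])
    def test_star_disconnects_after_centre(self, k):
        g = labelled(nx.star_graph(k))
        res = robustness(g.nodes, g.edges)
        assert res.n_removed == 1
        assert res.R == pytest.approx(1 / (k + 1))

    def test_path_of_three(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        res = robustness(g.nodes, g.edges)
        assert res.n_removed == 1
        assert res.R == pytest.approx(1 / 3)

    def test_single_node_scores_one(self):
        assert robustness(["x"], []).R == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            robustness([], [])

    def test_disconnected_raises(self):
        with pytest.raises(ValueError):
            robustness(["a", "b"], [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_result_bounds_on_random_connected_graphs(self, seed):
        g = labelled(nx.gnp_random_graph(9, 0.5, seed=seed))
        if g.number_of_nodes() == 0 or not nx.is_connected(g):
            g = labelled(nx.path_graph(5))
        res = robustness(g.nodes, g.edges)
        assert 1 <= res.n_removed <= res.initial_size
        assert 0.0 < res.R <= 1.0


sets_st = st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=8)


class TestNeighbourAffinity:
    def test_identical_sets(self):
        assert neighbour_affinity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert neighbour_affinity({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert neighbour_affinity({"a", "b"}, {"b", "c"}) == pytest.approx(0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            neighbour_affinity(set(), {"a"})

    @given(sets_st, sets_st)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        na = neighbour_affinity(a, b)
        assert na == neighbour_affinity(b, a)
        assert 0.0 <= na <= 1.0
        assert (na == 1.0) == (a == b)
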