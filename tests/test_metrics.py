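"""Centrality and efficiency metrics against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netres.construct import connected_component_sizes
from netres.metrics import (
    betweenness_centrality,
    degree_centrality,
    eigenvector_centrality,
    giant_component,
    global_efficiency,
    leverage_centrality,
    local_efficiency,
)
from netres.networks import BinaryNetwork, SignedWeightedNetwork

from conftest import random_binary


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Path-enumeration oracle (endpoints excluded, unnormalized)."""
    out = {n: 0.0 for n in g.nodes()}
    for s, t in itertools.combinations(g.nodes(), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def naive_global_efficiency(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    acc = 0.0
    for s, t in itertools.permutations(g.nodes(), 2):
        try:
            acc += 1.0 / nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            pass
    return acc / (n * (n - 1))


class TestDegree:
    def test_star_and_handshake(self, star4):
        scores = degree_centrality(star4).scores
        assert scores[0] == 4 and all(scores[i] == 1 for i in range(1, 5))
        assert sum(scores.values()) == 2 * star4.n_edges

    def test_signed_strength_sums_absolute_weights(self):
        net = SignedWeightedNetwork.from_weighted_edges(
            ["a", "b", "c"], [("a", "b", 0.5), ("a", "c", -0.3)]
        )
        assert degree_centrality(net).scores["a"] == pytest.approx(0.8)


class TestLeverage:
    def test_star_closed_form(self, star4):
        scores = leverage_centrality(star4).scores
        assert scores[0] == pytest.approx(0.6)
        assert scores[1] == pytest.approx(-0.6)

    def test_path3_closed_form(self, path3):
        scores = leverage_centrality(path3).scores
        assert scores[1] == pytest.approx(1 / 3)
        assert scores[0] == pytest.approx(-1 / 3)

    def test_regular_graph_zero(self):
        net = BinaryNetwork(nx.cycle_graph(8))
        assert all(v == pytest.approx(0.0) for v in leverage_centrality(net).scores.values())

    def test_isolated_node_flagged_minus_one(self):
        net = BinaryNetwork.from_edges([0, 1, 2], [(0, 1)])
        res = leverage_centrality(net)
        assert res.scores[2] == -1.0
        assert res.flags[2] == "isolated"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        net = random_binary(12, 0.3, seed)
        assert all(-1 <= v <= 1 for v in leverage_centrality(net).scores.values())


class TestEigenvector:
    def test_complete_graph_uniform(self):
        net = BinaryNetwork(nx.complete_graph(5))
        scores = eigenvector_centrality(net).scores
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_star_ratio_sqrt_n(self, star4):
        scores = eigenvector_centrality(star4).scores
        assert scores[0] / scores[1] == pytest.approx(2.0, abs=1e-8)

    def test_matches_dense_eigendecomposition(self):
        for seed in range(10):
            net = random_binary(20, 0.25, seed)
            if net.n_edges == 0:
                continue
            got = eigenvector_centrality(net).as_array(net.node_ids)
            vals, vecs = np.linalg.eigh(net.adjacency())
            ref = np.abs(vecs[:, np.argmax(vals)])
            ref /= ref.max()
            np.testing.assert_allclose(got, ref, atol=1e-7)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_relabeling_invariance(self, seed):
        net = random_binary(10, 0.4, seed)
        if net.n_edges == 0:
            return
        perm = list(np.random.default_rng(seed).permutation(10))
        mapping = dict(zip(range(10), perm))
        relabeled = BinaryNetwork(nx.relabel_nodes(net.graph, mapping), perm)
        a = eigenvector_centrality(net).scores
        b = eigenvector_centrality(relabeled).scores
        for old, new in mapping.items():
            assert a[old] == pytest.approx(b[new], abs=1e-8)


class TestBetweenness:
    def test_path_and_star(self, path3, star4):
        assert betweenness_centrality(path3).scores[1] == pytest.approx(1.0)
        scores = betweenness_centrality(star4).scores
        assert scores[0] == pytest.approx(6.0)  # all C(4,2) leaf pairs
        assert scores[1] == 0.0

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            net = random_binary(n, float(rng.uniform(0.2, 0.8)), int(rng.integers(2**31)))
            got = betweenness_centrality(net).scores
            ref = brute_force_betweenness(net.graph)
            for node in net.node_ids:
                assert got[node] == pytest.approx(ref[node], abs=1e-9)

    def test_weighted_cost_conventions_differ(self):
        # |r| as cost ranks the weak edge as the cheap one; 1/|r| reverses it
        net = SignedWeightedNetwork.from_weighted_edges(
            ["a", "m", "b", "x"],
            [("a", "m", 0.1), ("m", "b", 0.1), ("a", "x", 0.9), ("x", "b", 0.9)],
        )
        lit = betweenness_centrality(net, weighted_cost="abs").scores
        inv = betweenness_centrality(net, weighted_cost="inv").scores
        assert lit["m"] > lit["x"]
        assert inv["x"] > inv["m"]


class TestStructuralMetrics:
    def test_giant_component_cases(self, k3):
        assert giant_component(k3) == 3
        two_triangles = BinaryNetwork.from_edges(
            range(6), [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
        )
        assert giant_component(two_triangles) == 3
        assert giant_component(BinaryNetwork(nx.Graph())) == 0

    def test_giant_component_matches_component_size_oracle(self):
        for seed in range(10):
            net = random_binary(30, 0.05, seed)
            sizes = connected_component_sizes(net.adjacency())
            assert giant_component(net) == sizes.max()

    def test_global_efficiency_closed_forms(self, k3, path3):
        assert global_efficiency(k3) == pytest.approx(1.0)
        assert global_efficiency(path3) == pytest.approx(5 / 6)
        two_k2 = BinaryNetwork.from_edges(range(4), [(0, 1), (2, 3)])
        assert global_efficiency(two_k2) == pytest.approx(1 / 3)

    def test_local_efficiency_closed_forms(self, k3, star4):
        assert local_efficiency(k3) == pytest.approx(1.0)
        assert local_efficiency(star4) == 0.0

    def test_efficiencies_match_naive_oracle(self):
        for seed in range(10):
            net = random_binary(30, 0.15, seed)
            assert global_efficiency(net) == pytest.approx(
                naive_global_efficiency(net.graph), abs=1e-12
            )
            acc = 0.0
            for u in net.graph.nodes():
                nbrs = list(net.graph.neighbors(u))
                if len(nbrs) >= 2:
                    acc += naive_global_efficiency(net.graph.subgraph(nbrs))
            assert local_efficiency(net) == pytest.approx(acc / 30, abs=1e-12)

    def test_global_efficiency_non_increasing_under_edge_deletion(self):
        net = random_binary(20, 0.3, 4)
        e = next(iter(net.graph.edges()))
        g2 = net.graph.copy()
        g2.remove_edge(*e)
        assert global_efficiency(BinaryNetwork(g2, net.node_ids)) <= global_efficiency(net)
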