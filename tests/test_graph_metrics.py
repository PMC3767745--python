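"""Weighted topology metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from ssvepnet import (
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    mean_connectivity,
    network_metrics,
    node_degrees,
    shortest_path_lengths,
)
from ssvepnet.graph_metrics import DisconnectedNetworkError

from conftest import make_network, random_network
from oracles import (
    bf_clustering,
    bf_degrees,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_shortest_paths,
)


def tri(w_ab=1.0, w_bc=1.0, w_ac=1.0, extra=0):
    n = 3 + extra
    w = np.zeros((n, n))
    w[0, 1] = w[1, 0] = w_ab
    w[1, 2] = w[2, 1] = w_bc
    w[0, 2] = w[2, 0] = w_ac
    return w


class TestClosedForms:
    def test_degrees_path_graph(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        assert node_degrees(make_network(w)).tolist() == [1, 2, 2, 1]

    def test_degrees_complete_and_empty(self):
        n = 18
        w = 1.0 - np.eye(n)
        assert node_degrees(make_network(w)).tolist() == [n - 1] * n
        assert node_degrees(make_network(np.zeros((n, n)))).tolist() == [0] * n

    def test_unit_triangle_clusters_perfectly(self):
        per, mean = clustering_coefficient(make_network(tri()))
        assert np.allclose(per, 1.0)
        assert mean == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        _, mean = clustering_coefficient(make_network(w))
        assert mean == 0.0

    def test_weighted_triangle_cube_root(self):
        # each node's triple product is 1*1*0.5 -> C_i = 0.5**(1/3)
        per, _ = clustering_coefficient(make_network(tri(1.0, 1.0, 0.5)))
        assert np.allclose(per, 0.5 ** (1 / 3))

    def test_two_nodes_reciprocal_length(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        net = make_network(w, labels=["a", "b"])
        assert shortest_path_lengths(net)[0, 1] == pytest.approx(2.0)
        assert characteristic_path_length(net) == pytest.approx(2.0)

    def test_detour_beats_weak_direct_edge(self):
        # chain a-b-c with w=1 (length 2) vs direct a-c with w=0.4 (length 2.5)
        w = tri(1.0, 1.0, 0.4)
        dist = shortest_path_lengths(make_network(w))
        assert dist[0, 2] == pytest.approx(2.0)

    def test_disconnected_pair_is_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        dist = shortest_path_lengths(make_network(w))
        assert np.isinf(dist[0, 2])

    def test_complete_unit_graph_efficiency_one(self):
        w = 1.0 - np.eye(5)
        net = make_network(w)
        assert global_efficiency(net) == pytest.approx(1.0)
        assert characteristic_path_length(net) == pytest.approx(1.0)
        _, e_loc = local_efficiency(net)
        assert e_loc == pytest.approx(1.0)

    def test_unit_star_efficiency(self):
        # 4-node star: 6 ordered pairs at distance 1, 6 at distance 2
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert global_efficiency(make_network(w)) == pytest.approx(0.75)
        _, e_loc = local_efficiency(make_network(w))
        assert e_loc == 0.0

    def test_triangle_with_pendant_local_efficiency(self):
        w = tri(extra=1)
        w[2, 3] = w[3, 2] = 1.0
        per, _ = local_efficiency(make_network(w))
        assert per[0] == pytest.approx(1.0)
        assert per[1] == pytest.approx(1.0)
        assert per[3] == 0.0

    def test_empty_graph_efficiency_zero(self):
        assert global_efficiency(make_network(np.zeros((4, 4)))) == 0.0

    def test_fully_disconnected_path_length_signals(self):
        with pytest.raises(DisconnectedNetworkError):
            characteristic_path_length(make_network(np.zeros((4, 4))))

    def test_mean_connectivity_counts_present_edges_only(self):
        w = tri(0.6, 0.2, 0.0)
        assert mean_connectivity(make_network(w)) == pytest.approx(0.4)
        assert mean_connectivity(make_network(np.zeros((3, 3)))) == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            net = random_network(rng, n)
            w = net.weights
            assert np.array_equal(node_degrees(net), bf_degrees(w))
            per_c, mean_c = clustering_coefficient(net)
            bf_per_c, bf_mean_c = bf_clustering(w)
            assert np.allclose(per_c, bf_per_c, atol=1e-9)
            assert mean_c == pytest.approx(bf_mean_c, abs=1e-9)
            assert np.allclose(
                shortest_path_lengths(net), bf_shortest_paths(w), atol=1e-9
            )
            assert global_efficiency(net) == pytest.approx(
                bf_global_efficiency(w), abs=1e-9
            )
            per_l, mean_l = local_efficiency(net)
            bf_per_l, bf_mean_l = bf_local_efficiency(w)
            assert np.allclose(per_l, bf_per_l, atol=1e-9)
            assert mean_l == pytest.approx(bf_mean_l, abs=1e-9)

    def test_efficiency_is_inverse_of_path_length(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            net = random_network(rng, n, p_edge=0.7)
            prod = global_efficiency(net) * characteristic_path_length(net)
            assert prod == pytest.approx(1.0, abs=1e-12)

    def test_adding_an_edge_never_decreases_global_efficiency(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 8))
            net = random_network(rng, n, p_edge=0.4)
            w = net.weights.copy()
            zeros = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if w[i, j] == 0]
            if not zeros:
                continue
            i, j = zeros[int(rng.integers(len(zeros)))]
            before = global_efficiency(make_network(w))
            w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
            after = global_efficiency(make_network(w))
            assert after >= before - 1e-12

    def test_metrics_finite_with_isolated_nodes(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.4
        tm = network_metrics(make_network(w))
        assert np.isfinite(tm.path_length)
        assert tm.global_eff > 0
        assert np.isfinite(tm.clustering)
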