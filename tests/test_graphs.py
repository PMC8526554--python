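"""Graph metrics against brute-force oracles and known closed forms."""

import numpy as np
import pytest

from dynstates.errors import ComputationError, InputError
from dynstates.graphs import (BinaryGraph, assortativity, betweenness,
                              clustering_coefficients, global_efficiency,
                              metric_auc, profile_for_matrix,
                              proportional_threshold, small_worldness)
from oracles import (assortativity_brute, betweenness_brute, clustering_brute,
                     global_efficiency_brute, random_binary_graph)


def graph_from(adj):
    return BinaryGraph(np.asarray(adj))


STAR5 = np.zeros((5, 5), dtype=int)
STAR5[0, 1:] = STAR5[1:, 0] = 1
CYCLE4 = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]])
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
TRIANGLE = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
K4 = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)


class TestThresholding:
    def test_edge_count_rounding(self, rng):
        m = rng.standard_normal((10, 10))
        m = (m + m.T) / 2
        g = proportional_threshold(m, 20)
        assert g.n_edges == 9  # round(0.2 * 45)

    def test_tie_break_lexicographic(self):
        m = np.ones((4, 4)) - np.eye(4)
        g = proportional_threshold(m, 34)  # round(0.34*6) = 2 edges
        assert g.n_edges == 2
        assert g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 1

    def test_nestedness(self, rng):
        m = rng.standard_normal((12, 12))
        m = (m + m.T) / 2
        low = proportional_threshold(m, 10).adjacency
        high = proportional_threshold(m, 34).adjacency
        assert np.all(high[low == 1] == 1)

    @pytest.mark.parametrize("p", [0, 100, -5, 120])
    def test_out_of_range_threshold(self, p):
        with pytest.raises(InputError):
            proportional_threshold(np.eye(4), p)

    def test_edge_count_exact_across_grid(self, rng):
        m = rng.standard_normal((25, 25))
        m = (m + m.T) / 2
        for p in range(10, 35):
            g = proportional_threshold(m, p)
            assert g.n_edges == int(np.floor(p / 100 * 300 + 0.5))


class TestClosedForms:
    def test_complete_graph_efficiency(self):
        assert global_efficiency(graph_from(K4)) == pytest.approx(1.0)

    def test_path_graph_efficiency(self):
        assert global_efficiency(graph_from(PATH3)) == pytest.approx(5 / 6)

    def test_empty_graph_efficiency(self):
        assert global_efficiency(graph_from(np.zeros((4, 4)))) == 0.0

    def test_star_assortativity(self):
        assert assortativity(graph_from(STAR5)) == pytest.approx(-1.0)

    def test_regular_graph_assortativity_undefined(self):
        assert np.isnan(assortativity(graph_from(CYCLE4)))

    def test_edgeless_assortativity_errors(self):
        with pytest.raises(ComputationError):
            assortativity(graph_from(np.zeros((3, 3))))

    def test_triangle_clustering(self):
        assert np.allclose(clustering_coefficients(graph_from(TRIANGLE)), 1.0)

    def test_path_middle_clustering_zero(self):
        assert clustering_coefficients(graph_from(PATH3))[1] == 0.0

    def test_star_betweenness(self):
        bc = betweenness(graph_from(STAR5))
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)

    def test_cycle4_betweenness(self):
        # two equal shortest paths between opposite corners: each interior
        # node carries 1/2 of one pair, normalizer (R-1)(R-2)/2 = 3
        assert np.allclose(betweenness(graph_from(CYCLE4)), 1 / 6)


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(5, 13))
            adj = random_binary_graph(n, rng.uniform(0.2, 0.7), rng)
            if adj.sum() == 0:
                continue
            g = graph_from(adj)
            assert global_efficiency(g) == pytest.approx(
                global_efficiency_brute(adj), abs=1e-9)
            a_pkg, a_ref = assortativity(g), assortativity_brute(adj)
            assert (np.isnan(a_pkg) and np.isnan(a_ref)) or \
                a_pkg == pytest.approx(a_ref, abs=1e-9)
            assert np.allclose(clustering_coefficients(g),
                               clustering_brute(adj), atol=1e-12)
            if n >= 3:
                assert np.allclose(betweenness(g), betweenness_brute(adj),
                                   atol=1e-9)
            checked += 1
        assert checked >= 95


class TestSmallWorldness:
    def test_rewired_ring_lattice_is_small_world(self, rng):
        n, k = 50, 6
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                adj[i, j] = adj[j, i] = 1
        # rewire ~5% of edges into shortcuts
        edges = np.argwhere(np.triu(adj))
        for i, j in edges[rng.random(len(edges)) < 0.05]:
            adj[i, j] = adj[j, i] = 0
            while True:
                a, b = rng.integers(n, size=2)
                if a != b and not adj[a, b]:
                    adj[a, b] = adj[b, a] = 1
                    break
        sigma = small_worldness(graph_from(adj), n_null=20, seed=1)
        assert sigma > 1

    def test_dense_random_graph_near_unity(self, rng):
        adj = random_binary_graph(50, 0.5, rng)
        sigma = small_worldness(graph_from(adj), n_null=20, seed=2)
        assert sigma == pytest.approx(1.0, abs=0.2)

    def test_deterministic_given_seed(self, rng):
        adj = random_binary_graph(20, 0.3, rng)
        s1 = small_worldness(graph_from(adj), n_null=10, seed=3)
        s2 = small_worldness(graph_from(adj), n_null=10, seed=3)
        assert s1 == s2


class TestAuc:
    GRID = tuple(range(10, 35))

    def test_constant_rectangle(self):
        assert metric_auc(np.ones(25), self.GRID) == pytest.approx(0.24)

    def test_linear_ramp(self):
        assert metric_auc(np.linspace(0, 1, 25), self.GRID) == pytest.approx(0.12)

    def test_interior_missing_drops_both_segments(self):
        vals = np.ones(25)
        vals[10] = np.nan
        expected = 0.0
        t = np.asarray(self.GRID) / 100
        for i in range(24):
            if i not in (9, 10):
                expected += 0.5 * (t[i + 1] - t[i]) * 2
        assert metric_auc(vals, self.GRID) == pytest.approx(expected)

    def test_single_threshold_errors(self):
        with pytest.raises(InputError):
            metric_auc([1.0], [10])


class TestProfile:
    def test_25_graphs_and_determinism(self, rng):
        m = rng.standard_normal((25, 25))
        m = (m + m.T) / 2
        grid = tuple(float(p) for p in range(10, 35))
        p1 = profile_for_matrix(m, grid)
        p2 = profile_for_matrix(m, grid)
        assert len(p1.global_efficiency) == 25
        assert np.array_equal(p1.global_efficiency, p2.global_efficiency)
        assert p1.auc["assortativity"] == p2.auc["assortativity"]

    def test_region_permutation_equivariance(self, rng):
        m = rng.standard_normal((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        perm = rng.permutation(10)
        grid = (10.0, 20.0, 30.0)
        base = profile_for_matrix(m, grid)
        permuted = profile_for_matrix(m[np.ix_(perm, perm)], grid)
        assert np.allclose(permuted.clustering_coeff, base.clustering_coeff[:, perm])
        assert np.allclose(permuted.global_efficiency, base.global_efficiency)

    def test_efficiency_monotone_in_threshold(self, rng):
        m = rng.standard_normal((15, 15))
        m = (m + m.T) / 2
        prof = profile_for_matrix(m, tuple(float(p) for p in range(10, 35)))
        assert np.all(np.diff(prof.global_efficiency) >= -1e-12)
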