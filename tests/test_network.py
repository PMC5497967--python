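"""Density thresholding, graph metrics, null ensembles, small-world index."""

import itertools

import networkx as nx
import numpy as np
import pytest

from afnet import (
    MIMatrix,
    NullEnsembleCache,
    average_clustering,
    average_degree,
    build_null_ensemble,
    characteristic_path_length,
    count_edges,
    compute_metrics,
    density_sweep,
    giant_component_size,
    normalized_metrics,
    small_world_index,
    threshold_by_density,
)
from afnet.network import DEFAULT_DENSITY_GRID, UndefinedMetricError


def _mi_from_values(n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return MIMatrix(v)


def _adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


class TestThresholding:
    def test_full_density_on_64_nodes_gives_complete_graph(self):
        net = threshold_by_density(_mi_from_values(64), 1.0)
        assert count_edges(net) == 2016
        assert average_degree(net) == 63.0

    def test_density_010_on_64_nodes_keeps_202_edges(self):
        net = threshold_by_density(_mi_from_values(64), 0.1)
        assert count_edges(net) == 202  # round(0.1 * 2016), half-up

    def test_top_half_of_four_nodes_matches_enumeration(self):
        v = np.array([
            [0.0, 0.9, 0.2, 0.5],
            [0.9, 0.0, 0.7, 0.1],
            [0.2, 0.7, 0.0, 0.4],
            [0.5, 0.1, 0.4, 0.0],
        ])
        net = threshold_by_density(MIMatrix(v), 0.5)
        # brute force: rank all 6 pairs, keep top 3
        pairs = sorted(
            ((v[i, j], (i, j)) for i, j in itertools.combinations(range(4), 2)),
            reverse=True,
        )
        expected = {p for _, p in pairs[:3]}
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(net.adjacency, 1)))}
        assert kept == expected
        assert net.threshold_value == pytest.approx(pairs[2][0])

    def test_zero_edge_density_warns_but_returns_valid(self):
        with pytest.warns(UserWarning):
            net = threshold_by_density(_mi_from_values(4), 0.01)
        assert count_edges(net) == 0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_density_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            threshold_by_density(_mi_from_values(4), bad)

    def test_threshold_nesting_across_densities(self):
        mi = _mi_from_values(20, seed=3)
        prev = None
        for d in (0.1, 0.2, 0.3, 0.5, 0.9):
            net = threshold_by_density(mi, d)
            if prev is not None:
                assert np.all(prev.adjacency <= net.adjacency)
            prev = net


class TestSimpleMetrics:
    def test_complete_graph_counts(self):
        a = 1 - np.eye(64, dtype=int)
        assert count_edges(a) == 2016
        assert average_degree(a) == 63.0

    def test_empty_graph_counts(self):
        a = np.zeros((5, 5), dtype=int)
        assert count_edges(a) == 0
        assert average_degree(a) == 0.0
        assert giant_component_size(a) == 1

    def test_cycle_on_ten_nodes(self):
        a = _adj_from_edges(10, [(i, (i + 1) % 10) for i in range(10)])
        assert count_edges(a) == 10
        assert average_degree(a) == 2.0
        assert giant_component_size(a) == 10
        assert average_clustering(a) == 0.0

    def test_disjoint_cliques_giant_is_larger_clique(self):
        edges = list(itertools.combinations(range(5), 2)) + list(
            itertools.combinations(range(5, 8), 2)
        )
        a = _adj_from_edges(8, edges)
        assert giant_component_size(a) == 5

    def test_triangle_plus_pendant_clustering(self):
        # local coefficients (1, 1, 1, 0) -> mean 0.75
        a = _adj_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])
        assert average_clustering(a) == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_complete_graph_clustering_and_path_length(self):
        a = 1 - np.eye(6, dtype=int)
        assert average_clustering(a) == 1.0
        assert characteristic_path_length(a) == 1.0

    def test_cycle_six_path_length(self):
        a = _adj_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert characteristic_path_length(a) == pytest.approx(1.8)

    def test_disjoint_edges_exclude_unreachable_pairs(self):
        a = _adj_from_edges(4, [(0, 1), (2, 3)])
        assert characteristic_path_length(a) == 1.0

    def test_no_edges_path_length_undefined(self):
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(np.zeros((4, 4), dtype=int))

    def test_giant_mode_restricts_to_largest_component(self):
        # path on 3 nodes plus a disjoint edge
        a = _adj_from_edges(5, [(0, 1), (1, 2), (3, 4)])
        # reachable: distances 1,1,2 within path + 1 in the dyad -> 1.25
        assert characteristic_path_length(a) == pytest.approx(1.25)
        assert characteristic_path_length(a, mode="giant") == pytest.approx(4 / 3)


class TestOracleEquivalence:
    """Metrics match brute force and networkx on sampled small graphs."""

    @staticmethod
    def _brute_force(a):
        n = a.shape[0]
        # clustering by exhaustive triangle counting
        locals_ = []
        for v in range(n):
            nbrs = [u for u in range(n) if a[v, u]]
            d = len(nbrs)
            if d < 2:
                locals_.append(0.0)
                continue
            links = sum(
                a[u, w] for u, w in itertools.combinations(nbrs, 2)
            )
            locals_.append(2 * links / (d * (d - 1)))
        # all-pairs shortest paths by Floyd-Warshall
        dist = np.where(a > 0, 1.0, np.inf)
        np.fill_diagonal(dist, 0.0)
        for k in range(n):
            dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
        iu = np.triu_indices(n, 1)
        finite = dist[iu][np.isfinite(dist[iu])]
        cpl = finite.mean() if len(finite) else None
        # components by label propagation over the distance matrix
        giant = max(
            np.sum(np.isfinite(dist[v])) for v in range(n)
        )
        return float(np.mean(locals_)), cpl, int(giant)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_graphs_match_brute_force_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            p = rng.uniform(0.1, 0.9)
            a = (rng.random((n, n)) < p).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            c_bf, l_bf, g_bf = self._brute_force(a)
            assert average_clustering(a) == pytest.approx(c_bf)
            assert giant_component_size(a) == g_bf
            g = nx.from_numpy_array(a)
            assert average_clustering(a) == pytest.approx(nx.average_clustering(g))
            if l_bf is not None:
                assert characteristic_path_length(a) == pytest.approx(l_bf)


class TestNullEnsemble:
    def test_complete_graph_null_is_degenerate(self):
        null = build_null_ensemble(6, 15, ensemble_size=10, seed=0)
        assert null.mean_C_rand == 1.0
        assert null.mean_L_rand == 1.0
        assert null.sd_C_rand == 0.0

    def test_er_clustering_matches_analytic_expectation(self):
        # E[C] ~ density for G(n, m)
        null = build_null_ensemble(64, 605, ensemble_size=100, seed=1)
        expected = 605 / 2016
        assert null.mean_C_rand == pytest.approx(expected, abs=3 * null.sd_C_rand)

    def test_fixed_seed_reproduces_stats(self):
        a = build_null_ensemble(20, 40, ensemble_size=20, seed=7)
        b = build_null_ensemble(20, 40, ensemble_size=20, seed=7)
        assert a.mean_C_rand == b.mean_C_rand
        assert np.array_equal(a.sigma_rand_values, b.sigma_rand_values)

    def test_edge_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_null_ensemble(4, 7)


class TestNormalization:
    def test_complete_graph_normalizes_to_unity(self):
        a = 1 - np.eye(8, dtype=int)
        null = build_null_ensemble(8, 28, ensemble_size=10, seed=0)
        net = threshold_by_density(_mi_from_values(8), 1.0)
        assert normalized_metrics(net, null) == (1.0, 1.0)
        sigma, _ = small_world_index(net, null)
        assert sigma == 1.0

    def test_mismatched_null_rejected(self):
        net = threshold_by_density(_mi_from_values(8), 0.5)
        null = build_null_ensemble(8, 5, ensemble_size=10, seed=0)
        with pytest.raises(ValueError):
            normalized_metrics(net, null)

    def test_null_draw_normalizes_near_unity(self):
        # a graph drawn from its own null: C_norm, L_norm within 3 sd of 1
        null = build_null_ensemble(32, 100, ensemble_size=100, seed=3)
        rng = np.random.default_rng(10)
        from afnet.network import _gnm_adjacency

        hits = 0
        for _ in range(20):
            a = _gnm_adjacency(32, 100, rng)
            c_norm, l_norm = normalized_metrics(a, null)
            rel_c = null.sd_C_rand / null.mean_C_rand
            rel_l = null.sd_L_rand / null.mean_L_rand
            if abs(c_norm - 1) <= 3 * rel_c and abs(l_norm - 1) <= 3 * rel_l:
                hits += 1
        assert hits >= 18

    def test_watts_strogatz_detected_as_small_world(self):
        null = build_null_ensemble(64, 192, ensemble_size=100, seed=0)
        wins = 0
        for seed in range(10):
            g = nx.watts_strogatz_graph(64, 6, 0.05, seed=seed)
            a = nx.to_numpy_array(g, dtype=int)
            c_norm, _ = normalized_metrics(a, null)
            sigma, z = small_world_index(a, null)
            if c_norm > 1 and sigma > 1 and z > 2:
                wins += 1
        assert wins >= 9


class TestDensitySweep:
    def test_default_grid_has_21_points(self):
        assert len(DEFAULT_DENSITY_GRID) == 21
        assert DEFAULT_DENSITY_GRID[0] == 0.10
        assert DEFAULT_DENSITY_GRID[-1] == 0.30

    def test_edges_strictly_increase_and_giant_non_decreasing(self):
        mi = _mi_from_values(24, seed=5)
        cache = NullEnsembleCache(ensemble_size=20, seed=0)
        sweep = density_sweep(mi, (0.1, 0.15, 0.2, 0.25, 0.3), null_cache=cache)
        edges = [m.n_edges for _, m in sweep if m is not None]
        giants = [m.giant_component for _, m in sweep if m is not None]
        assert all(a < b for a, b in zip(edges, edges[1:]))
        assert all(a <= b for a, b in zip(giants, giants[1:]))

    def test_invalid_density_grid_rejected(self):
        with pytest.raises(ValueError):
            density_sweep(_mi_from_values(6), (0.1, 1.2))

    def test_sweep_survives_empty_network_densities(self):
        mi = _mi_from_values(5)
        with pytest.warns(UserWarning):
            sweep = density_sweep(mi, (0.01, 0.5), null_cache=NullEnsembleCache(10, 0))
        assert sweep[0][1] is None
        assert sweep[1][1] is not None
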