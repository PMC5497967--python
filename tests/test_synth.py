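"""Synthetic-data generator: layout, planted networks, signals, far field."""

import numpy as np
import pytest

from afnet import (
    GroundTruthNetwork,
    SimulationConfig,
    add_ventricular_farfield,
    generate_basket_layout,
    generate_planted_network,
    simulate_coupled_af,
)
from afnet.ksg import KSGParameters, ksg_mutual_information
from afnet.network import average_clustering


class TestBasketLayout:
    def test_full_basket_is_64_labels_a1_to_h8(self):
        layout = generate_basket_layout(8, 8)
        assert layout.n_channels == 64
        assert layout.labels[0] == "a1"
        assert layout.labels[-1] == "h8"
        assert len(set(layout.labels)) == 64

    def test_minimal_layout(self):
        assert generate_basket_layout(1, 1).labels == ("a1",)

    def test_labels_match_cross_product_in_spline_major_order(self):
        layout = generate_basket_layout(2, 3)
        expected = tuple(
            f"{s}{e}" for s in "ab" for e in (1, 2, 3)
        )  # brute-force cross product
        assert layout.labels == expected

    @pytest.mark.parametrize("splines,per", [(0, 8), (8, 0), (-1, 2)])
    def test_non_positive_counts_rejected(self, splines, per):
        with pytest.raises(ValueError):
            generate_basket_layout(splines, per)


class TestPlantedNetwork:
    def test_smallworld_preserves_ring_lattice_edge_count(self):
        net = generate_planted_network(64, "smallworld", k=6, p=0.05, seed=1)
        assert net.adjacency.sum() // 2 == 64 * 6 // 2  # n*k/2 edges
        # rewiring preserves connectivity with overwhelming probability
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(net.adjacency, directed=False)
        assert n_comp == 1

    def test_random_with_max_edges_is_complete(self):
        net = generate_planted_network(4, "random", m=6, seed=0)
        expected = 1 - np.eye(4)
        assert np.array_equal(net.adjacency, expected)

    def test_lattice_k2_is_triangle_free_cycle(self):
        net = generate_planted_network(10, "lattice", k=2)
        assert net.adjacency.sum() // 2 == 10
        assert (net.adjacency.sum(axis=1) == 2).all()
        assert average_clustering(net.adjacency) == 0.0

    def test_impossible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_network(4, "random", m=7, seed=0)

    def test_reproducible_under_seed(self):
        a = generate_planted_network(20, "random", m=30, seed=5)
        b = generate_planted_network(20, "random", m=30, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_coupling_only_on_edges(self):
        net = generate_planted_network(10, "random", m=12, coupling=0.7, seed=2)
        assert np.all(net.coupling_strength[net.adjacency == 0] == 0)
        assert np.allclose(net.coupling_strength[net.adjacency == 1], 0.7)

    def test_invalid_truth_rejected(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = 1  # asymmetric
        with pytest.raises(ValueError):
            GroundTruthNetwork(adj, adj * 0.5)

    def test_matching_is_disjoint_pairs(self):
        net = generate_planted_network(16, "matching", coupling=0.6, seed=1)
        assert (net.adjacency.sum(axis=1) <= 1).all()
        assert net.adjacency.sum() // 2 == 8

    def test_chains_cover_all_nodes_in_m_paths(self):
        net = generate_planted_network(15, "chains", m=3, seed=2)
        deg = net.adjacency.sum(axis=1)
        assert net.adjacency.sum() // 2 == 15 - 3  # n - m edges in m paths
        assert deg.max() == 2
        assert (deg == 1).sum() == 6  # two endpoints per chain

    def test_fragmented_chain_plus_dyads(self):
        net = generate_planted_network(15, "fragmented", k=7, m=3, seed=3)
        assert net.adjacency.sum() // 2 == 6 + 3  # chain edges + dyads
        assert (net.adjacency.sum(axis=1) == 0).sum() == 2  # free nodes

    def test_clustered_respects_corner_coupling_budget(self):
        from afnet.synth import generate_clustered_network

        for layout in ("random", "ring"):
            net = generate_clustered_network(
                15, n_bridges=7, triangle_coupling=0.3, bridge_coupling=0.4,
                bridge_layout=layout, seed=4,
            )
            budgets = net.coupling_strength.sum(axis=1)
            assert budgets.max() <= 1.0 + 1e-9
            # 5 disjoint triangles worth of local clustering
            from afnet.network import average_clustering

            assert average_clustering(net.adjacency) > 0.3

    def test_clustered_ring_layout_is_connected(self):
        from afnet.synth import generate_clustered_network
        from afnet.network import giant_component_size

        net = generate_clustered_network(15, n_bridges=7, bridge_layout="ring",
                                         seed=5)
        assert giant_component_size(net.adjacency) == 15


class TestSimulation:
    def test_sample_count_is_fs_times_duration(self):
        layout = generate_basket_layout(1, 2)
        adj = np.zeros((2, 2), dtype=int)
        truth = GroundTruthNetwork(adj, adj.astype(float))
        rec = simulate_coupled_af(layout, truth, SimulationConfig(seed=0))
        assert rec.n_samples == 58620  # 977 Hz x 60 s
        assert rec.n_channels == 2

    def test_deterministic_under_fixed_seed(self, small_layout, small_truth):
        cfg = SimulationConfig(duration_s=5.0, seed=9)
        a = simulate_coupled_af(small_layout, small_truth, cfg)
        b = simulate_coupled_af(small_layout, small_truth, cfg)
        assert np.array_equal(a.data, b.data)

    def test_node_count_mismatch_rejected(self, small_layout):
        adj = np.zeros((3, 3), dtype=int)
        truth = GroundTruthNetwork(adj, adj.astype(float))
        with pytest.raises(ValueError):
            simulate_coupled_af(small_layout, truth, SimulationConfig(duration_s=5))

    def test_duration_shorter_than_one_cycle_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=0.1)

    @staticmethod
    def _pair_mi(coupling: float, seed: int, duration: float = 6.0) -> tuple:
        """(linked MI, unlinked MI) on a 3-channel rig: 0-1 coupled, 2 free."""
        layout = generate_basket_layout(1, 3)
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        truth = GroundTruthNetwork(adj, adj * coupling)
        cfg = SimulationConfig(duration_s=duration, seed=seed)
        rec = simulate_coupled_af(layout, truth, cfg)
        p = KSGParameters(seed=seed)
        linked = ksg_mutual_information(rec.data[:, 0], rec.data[:, 1], p)
        unlinked = ksg_mutual_information(rec.data[:, 0], rec.data[:, 2], p)
        return linked, unlinked

    def test_full_coupling_beats_unlinked_pair_across_seeds(self):
        wins = sum(
            linked > unlinked
            for linked, unlinked in (self._pair_mi(1.0, s) for s in range(20))
        )
        assert wins >= 19

    def test_zero_coupling_indistinguishable_from_independence(self):
        diffs = [l - u for l, u in (self._pair_mi(0.0, s) for s in range(10))]
        # linked-pair excess MI centred on zero when no coupling is planted
        assert abs(np.mean(diffs)) < 0.01

    def test_mean_linked_mi_monotone_in_coupling(self):
        means = []
        for c in (0.2, 0.5, 0.8):
            means.append(np.mean([self._pair_mi(c, s)[0] for s in range(12)]))
        assert means[0] <= means[1] <= means[2]

    def test_marginal_amplitude_distributions_match(self):
        # pooled amplitude quantiles of coupled channels match free ones:
        # coupling moves event timing, not the per-channel waveform stats
        layout = generate_basket_layout(2, 6)
        adj = np.zeros((12, 12), dtype=int)
        for i, j in ((0, 1), (2, 3), (4, 5)):
            adj[i, j] = adj[j, i] = 1
        truth = GroundTruthNetwork(adj, adj * 0.8)
        rec = simulate_coupled_af(layout, truth,
                                  SimulationConfig(duration_s=20.0, seed=8))
        q = np.linspace(0.05, 0.95, 10)
        qa = np.quantile(rec.data[:, :6].ravel(), q)
        qb = np.quantile(rec.data[:, 6:].ravel(), q)
        assert np.allclose(qa, qb, atol=0.1)


class TestVentricularFarField:
    def test_zero_amplitude_is_identity(self, small_recording):
        cfg = SimulationConfig(duration_s=12.0, seed=3, ventricular_amplitude=0.0)
        out = add_ventricular_farfield(small_recording, cfg)
        assert np.array_equal(out.recording.data, small_recording.data)

    def test_contamination_is_scaled_template_at_r_times(self, small_recording):
        cfg = SimulationConfig(duration_s=12.0, seed=3)
        out = add_ventricular_farfield(small_recording, cfg)
        delta = out.recording.data - small_recording.data
        n_pre = int(round(50.0 * cfg.fs_hz / 1000.0))
        for r in out.r_peak_samples:
            lo, hi = r - n_pre, r - n_pre + len(out.template)
            if lo < 0 or hi > len(delta):
                continue
            for ch in range(delta.shape[1]):
                assert np.allclose(
                    delta[lo:hi, ch], out.channel_scales[ch] * out.template
                )
        # outside beats the recording is untouched
        mask = np.ones(len(delta), dtype=bool)
        for r in out.r_peak_samples:
            mask[max(0, r - n_pre) : r - n_pre + len(out.template)] = False
        assert np.allclose(delta[mask], 0.0)

    def test_beat_count_tracks_rr_interval(self):
        layout = generate_basket_layout(1, 2)
        adj = np.zeros((2, 2), dtype=int)
        truth = GroundTruthNetwork(adj, adj.astype(float))
        cfg = SimulationConfig(duration_s=60.0, rr_interval_ms=800.0,
                               rr_jitter_ms=0.0, seed=1)
        rec = simulate_coupled_af(layout, truth, cfg)
        out = add_ventricular_farfield(rec, cfg)
        assert 74 <= len(out.r_peak_samples) <= 76

    def test_rr_shorter_than_template_rejected(self, small_recording):
        cfg = SimulationConfig(duration_s=12.0, rr_interval_ms=400.0, seed=0)
        with pytest.raises(ValueError):
            add_ventricular_farfield(small_recording, cfg)

    def test_tuple_unpacking_yields_recording_and_ecg(self, contaminated):
        rec, ecg = contaminated
        assert rec.n_samples == len(ecg)
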