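"""Proximity graphs, modularity Q, and the spectral module decomposition,
checked against analytic values and an exhaustive partition-search oracle."""

import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from cavnet import (build_graph, decompose_blob, generate_blob, modularity_Q,
                    multi_pt_analysis, spectral_modules)

from oracles import exhaustive_max_modularity


def adjacency_from_edges(n, edges):
    W = np.zeros((n, n))
    for a, b in edges:
        W[a, b] = W[b, a] = 1.0
    return W


TRIANGLE_BRIDGE = adjacency_from_edges(
    6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
K4 = adjacency_from_edges(4, [(a, b) for a in range(4) for b in range(a)])


class TestBuildGraph:
    def test_linear_similarity_weight(self):
        pts = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        g = build_graph(pts, 60.0, weighting="linear")
        assert g.n_edges == 1
        assert g.adjacency[0, 1] == pytest.approx(1.0 - 50.0 / 60.0)  # 1/6

    def test_no_edge_beyond_threshold(self):
        pts = np.array([[0.0, 0, 0], [70.0, 0, 0]])
        g = build_graph(pts, 60.0)
        assert g.n_edges == 0

    def test_complete_graph_when_pt_exceeds_diameter(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 30, size=(8, 3))
        g = build_graph(pts, 100.0, weighting="binary")
        assert g.n_edges == 8 * 7 // 2
        assert np.array_equal(np.diag(g.adjacency), np.zeros(8))

    def test_gaussian_weight_uses_fixed_decay(self):
        pts = np.array([[0.0, 0, 0], [25.0, 0, 0]])
        g80 = build_graph(pts, 80.0, weighting="gaussian", decay=25.0)
        g160 = build_graph(pts, 160.0, weighting="gaussian", decay=25.0)
        assert g80.adjacency[0, 1] == pytest.approx(np.exp(-1.0))
        assert g80.adjacency[0, 1] == g160.adjacency[0, 1]


class TestModularityQ:
    def test_k4_single_community_is_zero(self):
        assert modularity_Q(K4, [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_two_triangles_with_bridge(self):
        q = modularity_Q(TRIANGLE_BRIDGE, [0, 0, 0, 1, 1, 1])
        assert q == pytest.approx(5.0 / 14.0)

    def test_k4_anticommunity_split_is_negative(self):
        assert modularity_Q(K4, [0, 0, 1, 1]) == pytest.approx(-1.0 / 6.0)

    def test_zero_weight_graph_defined_zero(self):
        assert modularity_Q(np.zeros((3, 3)), [0, 1, 2]) == 0.0

    def test_partition_must_be_total(self):
        with pytest.raises(ValueError):
            modularity_Q(K4, [0, 0, 0])


class TestSpectralModules:
    def test_complete_graph_indivisible(self):
        dec = spectral_modules(nx.complete_graph(4))
        assert dec.n_modules == 1
        assert dec.q == pytest.approx(0.0)

    def test_two_triangles_with_bridge_recovered(self):
        g = nx.from_numpy_array(TRIANGLE_BRIDGE)
        dec = spectral_modules(g)
        assert dec.n_modules == 2
        assert dec.q == pytest.approx(5.0 / 14.0)
        assert adjusted_rand_score(dec.partition, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_planted_spatial_clusters_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 8, size=(10, 3))
        b = rng.uniform(0, 8, size=(10, 3)) + np.array([50.0, 0, 0])
        g = build_graph(np.vstack([a, b]), 80.0)
        dec = spectral_modules(g)
        truth = [0] * 10 + [1] * 10
        assert dec.n_modules == 2
        assert adjusted_rand_score(dec.partition, truth) == 1.0

    def test_rejects_disconnected_graph(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            spectral_modules(g)

    @pytest.mark.parametrize("seed", range(6))
    def test_against_exhaustive_partition_search(self, seed):
        # random geometric graphs, small enough for full enumeration
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        while True:
            pts = rng.uniform(0, 60, size=(n, 3))
            g = build_graph(pts, 45.0)
            gx = g.to_networkx()
            if gx.number_of_edges() and nx.is_connected(gx):
                break
        dec = spectral_modules(g)
        best_q, _ = exhaustive_max_modularity(g.adjacency)
        assert dec.q <= best_q + 1e-12
        assert dec.q >= 0.95 * best_q - 1e-12

    def test_partition_invariant_to_node_order_and_rigid_motion(self):
        blob = generate_blob("S2", 7)
        pts = blob.molecule_positions
        dec = decompose_blob(pts, 80.0)
        perm = np.random.default_rng(1).permutation(len(pts))
        dec_perm = decompose_blob(pts[perm], 80.0)
        assert adjusted_rand_score(dec.partition[perm], dec_perm.partition) == 1.0
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        dec_rot = decompose_blob(pts @ rot.T + np.array([100.0, -50.0, 30.0]),
                                 80.0)
        assert adjusted_rand_score(dec.partition, dec_rot.partition) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_q_never_below_single_community(self, seed):
        rng = np.random.default_rng(seed + 20)
        pts = rng.uniform(0, 100, size=(15, 3))
        dec = decompose_blob(pts, 300.0)
        assert dec.q >= -1e-12


class TestDecomposeBlob:
    def test_two_components_each_complete(self):
        pts = np.vstack([np.random.default_rng(0).uniform(0, 20, (6, 3)),
                         np.random.default_rng(1).uniform(0, 20, (5, 3))
                         + np.array([500.0, 0, 0])])
        dec = decompose_blob(pts, 80.0, weighting="binary")
        assert dec.n_modules == 2
        assert sorted(dec.module_sizes.tolist()) == [5, 6]

    def test_singleton_component_is_own_module(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0], [500.0, 0, 0]])
        dec = decompose_blob(pts, 80.0)
        assert dec.n_modules == 2
        assert dec.partition[2] != dec.partition[0]

    def test_caveola_seven_planted_subclusters(self):
        blob = generate_blob("CAV", 1)
        dec = decompose_blob(blob.molecule_positions, 80.0)
        assert dec.n_modules == 7
        assert adjusted_rand_score(dec.partition, blob.submodule_labels) == 1.0


class TestMultiPt:
    def test_all_singletons_below_min_distance(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]])
        table = multi_pt_analysis(pts, [10.0, 50.0])
        assert table["n_components"].tolist() == [3, 3]

    def test_single_component_above_diameter(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 50, size=(12, 3))
        table = multi_pt_analysis(pts, [200.0])
        assert table.loc[0, "n_components"] == 1
        assert table.loc[0, "mean_component_size"] == 12

    def test_component_count_non_increasing(self):
        blob = generate_blob("CAV", 4)
        table = multi_pt_analysis(blob.molecule_positions,
                                  [float(pt) for pt in range(10, 260, 10)])
        assert (np.diff(table["n_components"]) <= 0).all()

    def test_module_count_stable_over_pt_window(self):
        # module count must be constant across the 60-170 nm stability window
        blob = generate_blob("CAV", 6)
        table = multi_pt_analysis(blob.molecule_positions,
                                  [float(pt) for pt in range(60, 180, 10)])
        assert table["n_modules"].nunique() == 1
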