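"""Oracle and property tests for the spectral-wavelet embedding core."""

import networkx as nx
import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

import diffembed as de
from diffembed.graphwave import EmbeddingConfig
from .conftest import random_weighted_graph, weighted_graph_from_edges


class TestLaplacian:
    def test_two_node_closed_form(self, two_node_network):
        L, nodes = de.build_laplacian(two_node_network)
        w = 0.7
        assert nodes == ["a", "b"]
        assert np.allclose(L.toarray(), [[w, -w], [-w, w]])
        assert np.allclose(np.sort(scipy.linalg.eigvalsh(L.toarray())), [0, 2 * w])

    def test_edgeless_graph_is_zero(self):
        g = nx.empty_graph(4)
        net = de.WeightedPPINetwork(
            graph=nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}),
            condition_label="empty")
        L, _ = de.build_laplacian(net)
        assert L.count_nonzero() == 0

    def test_psd_with_zero_row_sums(self):
        rng = np.random.default_rng(0)
        net = random_weighted_graph(20, rng)
        L, _ = de.build_laplacian(net)
        dense = L.toarray()
        assert np.allclose(dense, dense.T)
        assert np.allclose(dense.sum(axis=1), 0)
        assert scipy.linalg.eigvalsh(dense).min() >= -1e-10


class TestScaleSelection:
    def test_formula_at_unit_eigenvalues(self):
        # single edge of weight 0.5: eigenvalues {0, 1}
        net = weighted_graph_from_edges([("a", "b", 0.5)])
        L, _ = de.build_laplacian(net)
        scales = de.select_scales(L, n_scales=2, eta_pair=(0.95, 0.70))
        assert scales[0] == pytest.approx(-np.log(0.95), rel=1e-9)  # ~0.0513
        assert scales[-1] == pytest.approx(-np.log(0.70), rel=1e-9)  # ~0.3567

    def test_two_scales_are_range_endpoints(self):
        rng = np.random.default_rng(1)
        net = random_weighted_graph(15, rng)
        L, _ = de.build_laplacian(net)
        lam = scipy.linalg.eigvalsh(L.toarray())
        lam2 = lam[lam > 1e-10].min()
        ref = np.sqrt(lam2 * lam.max())
        scales = de.select_scales(L, n_scales=2)
        assert scales[0] == pytest.approx(-np.log(0.95) / ref, rel=1e-6)
        assert scales[1] == pytest.approx(-np.log(0.70) / ref, rel=1e-6)

    def test_edgeless_graph_directs_to_manual_scales(self):
        net = de.WeightedPPINetwork(graph=nx.empty_graph(3), condition_label="x")
        L, _ = de.build_laplacian(net)
        with pytest.raises(ValueError, match="scales"):
            de.select_scales(L)

    def test_weight_scaling_invariance_of_embeddings(self):
        """Scaling all weights by c scales eigenvalues by c and auto scales by
        1/c, leaving the heat kernels — hence embeddings — unchanged."""
        rng = np.random.default_rng(2)
        net = random_weighted_graph(20, rng)
        scaled = de.WeightedPPINetwork(graph=net.graph.copy(), condition_label="s")
        for u, v, d in scaled.graph.edges(data=True):
            scaled.graph[u][v]["weight"] = d["weight"] * 3.7
        cfg = EmbeddingConfig()
        e1 = de.embed_network(net, cfg)
        e2 = de.embed_network(scaled, cfg)
        assert np.allclose(e1.vectors, e2.vectors, atol=1e-9)


class TestHeatWavelets:
    def test_edgeless_graph_identity(self):
        net = de.WeightedPPINetwork(graph=nx.empty_graph(5), condition_label="x")
        L, _ = de.build_laplacian(net)
        for s in (0.1, 1.0, 10.0):
            assert np.allclose(de.heat_wavelets(L, s), np.eye(5))

    def test_two_node_closed_form(self, two_node_network):
        L, _ = de.build_laplacian(two_node_network)
        s, w = 0.8, 0.7
        on = (1 + np.exp(-2 * s * w)) / 2
        off = (1 - np.exp(-2 * s * w)) / 2
        assert np.allclose(de.heat_wavelets(L, s), [[on, off], [off, on]], atol=1e-12)

    def test_matches_dense_eigendecomposition_oracle(self):
        """Exact backend vs a literal expm oracle on random 20-node graphs."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            net = random_weighted_graph(20, rng)
            L, _ = de.build_laplacian(net)
            s = float(rng.uniform(0.2, 2.0))
            oracle = scipy.linalg.expm(-s * L.toarray())
            psi = de.heat_wavelets(L, s)
            assert np.allclose(psi, oracle, atol=1e-10)
            assert np.allclose(psi.sum(axis=0), 1.0)
            assert psi.min() >= -1e-12 and psi.max() <= 1 + 1e-12

    def test_chebyshev_matches_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            net = random_weighted_graph(30, rng)
            L, _ = de.build_laplacian(net)
            s = float(rng.uniform(0.2, 1.5))
            exact = de.heat_wavelets(L, s, backend="exact")
            cheb = de.heat_wavelets(L, s, backend="chebyshev", chebyshev_order=50)
            assert np.max(np.abs(exact - cheb)) < 1e-6

    def test_invalid_inputs(self, two_node_network):
        L, _ = de.build_laplacian(two_node_network)
        with pytest.raises(ValueError):
            de.heat_wavelets(L, -1.0)
        with pytest.raises(ValueError):
            de.heat_wavelets(L, 1.0, backend="chebyshev", chebyshev_order=0)


class TestCharacteristicEmbedding:
    def test_t_zero_gives_one_zero(self):
        rng = np.random.default_rng(5)
        net = random_weighted_graph(10, rng)
        L, _ = de.build_laplacian(net)
        psi = de.heat_wavelets(L, 0.5)
        emb = de.characteristic_embedding([psi], [0.0, 1.0])
        assert np.allclose(emb[:, 0], 1.0)
        assert np.allclose(emb[:, 1], 0.0)

    def test_edgeless_closed_form(self):
        n = 6
        net = de.WeightedPPINetwork(graph=nx.empty_graph(n), condition_label="x")
        L, _ = de.build_laplacian(net)
        psi = de.heat_wavelets(L, 1.0)  # identity
        ts = [0.3, 2.0, 9.0]
        emb = de.characteristic_embedding([psi], ts)
        for k, t in enumerate(ts):
            assert np.allclose(emb[:, 2 * k], ((n - 1) + np.cos(t)) / n)
            assert np.allclose(emb[:, 2 * k + 1], np.sin(t) / n)

    def test_coordinates_bounded(self):
        rng = np.random.default_rng(6)
        net = random_weighted_graph(25, rng)
        emb = de.embed_network(net)
        assert emb.vectors.min() >= -1 - 1e-12
        assert emb.vectors.max() <= 1 + 1e-12


class TestEmbedNetwork:
    def test_rerun_is_bitwise_identical(self):
        rng = np.random.default_rng(7)
        net = random_weighted_graph(30, rng)
        e1 = de.embed_network(net)
        e2 = de.embed_network(net)
        assert np.max(np.abs(e1.vectors - e2.vectors)) == 0.0
        assert e1.fingerprint == e2.fingerprint

    def test_default_config_is_100_dimensional(self):
        rng = np.random.default_rng(8)
        net = random_weighted_graph(12, rng)
        assert de.embed_network(net).n_dims == 100

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        net = random_weighted_graph(30, rng)
        emb = de.embed_network(net)
        # relabel nodes; sorted node order changes, embeddings must follow
        mapping = {n: f"z{n}" for n in net.graph.nodes}
        relabeled = de.WeightedPPINetwork(
            graph=nx.relabel_nodes(net.graph, mapping), condition_label="perm")
        emb_p = de.embed_network(relabeled)
        lookup = dict(zip(emb_p.node_ids, emb_p.vectors))
        for node, vec in zip(emb.node_ids, emb.vectors):
            assert np.allclose(vec, lookup[mapping[node]], atol=1e-10)

    @pytest.mark.parametrize("maker,orbits", [
        (lambda: nx.star_graph(5), [[1, 2, 3, 4, 5]]),
        (lambda: nx.cycle_graph(6), [[0, 1, 2, 3, 4, 5]]),
        (lambda: nx.path_graph(3), [[0, 2]]),
    ])
    def test_automorphic_nodes_get_equal_embeddings(self, maker, orbits):
        g = maker()
        net = weighted_graph_from_edges([(f"n{u}", f"n{v}", 1.0) for u, v in g.edges])
        emb = de.embed_network(net)
        frame = emb.to_frame()
        for orbit in orbits:
            rows = frame.loc[[f"n{i}" for i in orbit]].to_numpy()
            assert np.allclose(rows - rows[0], 0.0, atol=1e-10)

    def test_identical_weights_identical_embeddings(self):
        rng = np.random.default_rng(10)
        net = random_weighted_graph(15, rng)
        twin = de.WeightedPPINetwork(graph=net.graph.copy(), condition_label="twin")
        assert np.array_equal(de.embed_network(net).vectors,
                              de.embed_network(twin).vectors)

    def test_explicit_scales_set_dimension(self):
        rng = np.random.default_rng(11)
        net = random_weighted_graph(8, rng)
        cfg = EmbeddingConfig(scales=(0.5, 1.0, 2.0))  # 3 scales x 25 t x 2 = 150
        emb = de.embed_network(net, cfg)
        assert emb.n_dims == 150  # n_dims follows the scales actually configured


class TestEmbedPair:
    def test_shared_scales_are_exchangeable(self):
        rng = np.random.default_rng(12)
        net_a = random_weighted_graph(20, rng)
        net_b = de.WeightedPPINetwork(graph=net_a.graph.copy(), condition_label="b")
        for u, v, d in net_b.graph.edges(data=True):
            net_b.graph[u][v]["weight"] = d["weight"] * float(rng.uniform(0.5, 1.5))
        e_ab = de.embed_pair(net_a, net_b)
        e_ba = de.embed_pair(net_b, net_a)
        assert np.array_equal(e_ab[0].vectors, e_ba[1].vectors)
        assert np.array_equal(e_ab[1].vectors, e_ba[0].vectors)

    def test_identical_networks_give_identical_embeddings(self):
        rng = np.random.default_rng(13)
        net = random_weighted_graph(18, rng)
        twin = de.WeightedPPINetwork(graph=net.graph.copy(), condition_label="t")
        e1, e2 = de.embed_pair(net, twin)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_mismatched_node_sets_raise(self):
        rng = np.random.default_rng(14)
        net_a = random_weighted_graph(10, rng)
        net_b = random_weighted_graph(11, rng)
        with pytest.raises(ValueError):
            de.embed_pair(net_a, net_b)
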