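"""Thresholding, topological metrics vs brute-force oracles, rewired
nulls, normalization, AUC curves, modularity, and hub scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphnet import graph
from morphnet.errors import UndefinedRatioError
from morphnet.graph import ThresholdedNetwork
from tests import _oracles


def random_similarity(rng, n):
    iu = np.triu_indices(n, k=1)
    m = np.zeros((n, n))
    m[iu] = rng.random(iu[0].size) * 0.9 + 0.05
    return m + m.T


def make_net(adj, weights=None):
    adj = np.asarray(adj, dtype=float)
    w = adj if weights is None else np.asarray(weights, dtype=float)
    return ThresholdedNetwork(
        adjacency_binary=(adj > 0).astype(np.uint8),
        adjacency_weighted=w,
        sparsity=0.0,
        kls_threshold=0.0,
        n_edges=int((adj > 0).sum() // 2),
    )


class TestThresholding:
    def test_example_edge_count(self, rng):
        net = graph.threshold_by_sparsity(random_similarity(rng, 10), 0.2)
        assert net.n_edges == 9  # round(0.2 * 45)
        assert net.adjacency_binary.sum() == 18

    @given(n=st.integers(5, 40), seed=st.integers(0, 1000), s_idx=st.integers(0, 17))
    def test_edge_count_exact_property(self, n, seed, s_idx):
        s = float(graph.DEFAULT_SPARSITIES[s_idx])
        m = random_similarity(np.random.default_rng(seed), n)
        net = graph.threshold_by_sparsity(m, s)
        assert net.adjacency_binary.sum() // 2 == graph.edge_count_for_sparsity(n, s)

    def test_saturation_gives_complete_graph(self, rng):
        m = random_similarity(rng, 6)
        net = graph.threshold_by_sparsity(m, 0.999999)
        iu = np.triu_indices(6, k=1)
        assert net.n_edges == 15
        assert np.isclose(net.kls_threshold, m[iu].min())

    def test_weighted_pattern_matches_binary(self, rng):
        m = random_similarity(rng, 12)
        net = graph.threshold_by_sparsity(m, 0.3)
        assert np.array_equal(net.adjacency_weighted > 0, net.adjacency_binary > 0)
        nz = net.adjacency_weighted > 0
        assert np.array_equal(net.adjacency_weighted[nz], m[nz])

    def test_invalid_sparsity_rejected(self, rng):
        with pytest.raises(ValueError):
            graph.threshold_by_sparsity(random_similarity(rng, 6), 1.5)


class TestMetricsClosedForms:
    def test_complete_graph(self):
        n = 7
        adj = np.ones((n, n)) - np.eye(n)
        net = make_net(adj)
        gm = graph.global_metrics(net, "binary")
        assert gm.cp == 1.0 and gm.lp == 1.0 and gm.eglob == 1.0

    def test_star_betweenness(self):
        n = 6
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        nm = graph.nodal_metrics(make_net(adj), "binary")
        assert nm.betweenness[0] == (n - 1) * (n - 2) / 2  # 10
        assert np.all(nm.betweenness[1:] == 0)

    def test_binary_and_weighted_degree_coincide_on_01_weights(self, rng):
        m = random_similarity(rng, 10)
        net = graph.threshold_by_sparsity(m, 0.3)
        binary01 = make_net(net.adjacency_binary.astype(float))
        nb = graph.nodal_metrics(binary01, "binary")
        nw = graph.nodal_metrics(binary01, "weighted")
        assert np.allclose(nb.degree, nw.degree)


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", ["binary", "weighted"])
    def test_random_graphs_match_brute_force(self, kind, rng):
        for _ in range(20):
            n = int(rng.integers(5, 13))
            m = random_similarity(rng, n)
            net = graph.threshold_by_sparsity(m, float(rng.uniform(0.15, 0.5)))
            adj = net.adjacency(kind)
            weighted = kind == "weighted"
            d = _oracles.floyd_warshall(_oracles.length_matrix(adj, weighted))
            gm = graph.global_metrics(net, kind)
            nm = graph.nodal_metrics(net, kind)
            assert np.isclose(gm.lp, _oracles.char_path_length(d), atol=1e-9)
            assert np.isclose(gm.eglob, _oracles.global_efficiency(d), atol=1e-9)
            assert np.isclose(gm.eloc, _oracles.local_efficiency(adj, weighted), atol=1e-9)
            cc = (
                _oracles.clustering_onnela(adj) if weighted else _oracles.clustering_binary(adj)
            )
            assert np.isclose(gm.cp, cc.mean(), atol=1e-9)
            assert np.allclose(nm.efficiency, _oracles.nodal_efficiency(d), atol=1e-9)
            assert np.allclose(nm.betweenness, _oracles.betweenness(adj, weighted), atol=1e-9)


class TestRewireNull:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        m = random_similarity(rng, 15)
        net = graph.threshold_by_sparsity(m, 0.25)
        nulls = graph.rewire_null(net, n_nulls=5, seed=0)
        deg = net.adjacency_binary.sum(axis=1)
        for nu in nulls:
            assert np.array_equal(np.sort(nu.adjacency_binary.sum(axis=1)), np.sort(deg))
            assert nu.adjacency_binary.sum() == net.adjacency_binary.sum()

    def test_weight_multiset_preserved(self, rng):
        m = random_similarity(rng, 12)
        net = graph.threshold_by_sparsity(m, 0.3)
        nulls = graph.rewire_null(net, n_nulls=3, seed=1)
        orig = np.sort(net.adjacency_weighted[net.adjacency_weighted > 0])
        for nu in nulls:
            assert np.allclose(np.sort(nu.adjacency_weighted[nu.adjacency_weighted > 0]), orig)

    def test_rewiring_destroys_clustering(self, rng):
        # two 6-cliques joined by one edge: highly clustered
        adj = np.zeros((12, 12))
        adj[:6, :6] = 1
        adj[6:, 6:] = 1
        np.fill_diagonal(adj, 0)
        adj[5, 6] = adj[6, 5] = 1
        net = make_net(adj)
        nulls = graph.rewire_null(net, n_nulls=30, seed=2)
        null_cp = np.median([graph.global_metrics(nu, "binary").cp for nu in nulls])
        assert null_cp < graph.global_metrics(net, "binary").cp

    def test_reproducible_given_seed(self, rng):
        m = random_similarity(rng, 10)
        net = graph.threshold_by_sparsity(m, 0.3)
        a = graph.rewire_null(net, n_nulls=2, seed=42)
        b = graph.rewire_null(net, n_nulls=2, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.adjacency_binary, y.adjacency_binary)
            assert np.array_equal(x.adjacency_weighted, y.adjacency_weighted)


class TestNormalizeMetrics:
    def test_self_normalization_is_unity(self, rng):
        m = random_similarity(rng, 10)
        net = graph.threshold_by_sparsity(m, 0.3)
        gm = graph.global_metrics(net, "binary")
        norm = graph.normalize_metrics(gm, [gm, gm])
        for entry in norm.values():
            assert np.isclose(entry["normalized"], 1.0)

    def test_invariant_to_metric_rescaling(self):
        from dataclasses import replace

        real = graph.GlobalMetrics(cp=0.4, lp=2.0, eloc=0.5, eglob=0.3)
        nulls = [graph.GlobalMetrics(cp=0.2, lp=1.8, eloc=0.4, eglob=0.35)]
        n1 = graph.normalize_metrics(real, nulls)
        scale = 3.7
        real2 = replace(real, cp=real.cp * scale)
        nulls2 = [replace(nulls[0], cp=nulls[0].cp * scale)]
        n2 = graph.normalize_metrics(real2, nulls2)
        assert np.isclose(n1["cp"]["normalized"], n2["cp"]["normalized"])

    def test_zero_null_mean_rejected(self):
        real = graph.GlobalMetrics(cp=0.4, lp=2.0, eloc=0.5, eglob=0.3)
        nulls = [graph.GlobalMetrics(cp=0.0, lp=1.0, eloc=1.0, eglob=1.0)]
        with pytest.raises(UndefinedRatioError):
            graph.normalize_metrics(real, nulls)


class TestMetricCurves:
    def test_constant_metric_rectangle_auc(self, monkeypatch, rng):
        m = random_similarity(rng, 20)
        s_grid = tuple(np.round(np.arange(0.05, 0.40, 0.02), 2))
        monkeypatch.setattr(
            graph, "global_metrics",
            lambda net, kind="binary", **kw: graph.GlobalMetrics(cp=2.0, lp=1, eloc=1, eglob=1),
        )
        curve = graph.metric_over_sparsity(m, "cp", s_grid, kind="binary")
        assert np.isclose(curve.auc, 2.0 * 0.34, atol=1e-12)

    def test_linear_metric_exact_trapezoid(self, monkeypatch, rng):
        m = random_similarity(rng, 20)
        s_grid = tuple(np.round(np.arange(0.05, 0.40, 0.02), 2))

        def fake(net, kind="binary", **kw):
            return graph.GlobalMetrics(cp=3.0 * net.sparsity + 1.0, lp=1, eloc=1, eglob=1)

        monkeypatch.setattr(graph, "global_metrics", fake)
        curve = graph.metric_over_sparsity(m, "cp", s_grid, kind="binary")
        exact = 3.0 / 2 * (0.39**2 - 0.05**2) + (0.39 - 0.05)
        assert np.isclose(curve.auc, exact, atol=1e-12)

    def test_single_point_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="at least two"):
            graph.metric_over_sparsity(random_similarity(rng, 10), "cp", (0.2,))

    def test_nodal_curve_gives_per_node_auc(self, rng):
        m = random_similarity(rng, 12)
        curve = graph.metric_over_sparsity(m, "degree", (0.1, 0.2, 0.3), kind="binary")
        assert curve.values.shape == (3, 12)
        assert np.asarray(curve.auc).shape == (12,)


class TestModularity:
    def test_two_cliques_newman_closed_form(self):
        adj = np.zeros((10, 10))
        adj[:5, :5] = 1
        adj[5:, 5:] = 1
        np.fill_diagonal(adj, 0)
        res = graph.modular_partition(make_net(adj), n_restarts=10, seed=0)
        assert np.isclose(res["q"], 0.5, atol=1e-12)  # 1 - 1/k for k equal modules
        assert res["n_modules"] == 2
        assert len(set(res["partition"][:5])) == 1
        assert len(set(res["partition"][5:])) == 1

    def test_complete_graph_has_no_structure(self):
        adj = np.ones((8, 8)) - np.eye(8)
        res = graph.modular_partition(make_net(adj), n_restarts=10, seed=0)
        assert res["q"] <= 1e-9

    def test_z_score_against_nulls(self, rng):
        m = random_similarity(rng, 14)
        net = graph.threshold_by_sparsity(m, 0.25)
        nulls = graph.rewire_null(net, n_nulls=8, seed=0)
        res = graph.modular_partition(net, n_restarts=10, seed=0, nulls=nulls)
        assert res["z_score"] is not None and np.isfinite(res["z_score"])


class TestHubScore:
    def test_flag_counts_for_atlas_sizes(self, rng):
        for n, expected in ((90, 9), (112, 11)):
            maps = [rng.random(n) for _ in range(6)]
            res = graph.hub_score(maps)
            assert res["n_flagged_per_map"] == expected
            for m in maps:
                assert graph.top_fraction_nodes(m).size == expected

    def test_consistent_top_node_scores_six(self, rng):
        maps = []
        for _ in range(6):
            m = rng.random(20)
            m[3] = 2.0  # always ranked first
            maps.append(m)
        res = graph.hub_score(maps)
        assert res["scores"][3] == 6
        assert 3 in res["hubs"]

    def test_tie_break_is_deterministic_first_indices(self):
        maps = [np.ones(20)] * 6
        res = graph.hub_score(maps)
        assert np.array_equal(np.flatnonzero(res["scores"] == 6), np.arange(2))
        assert res["n_flagged_per_map"] == 2
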