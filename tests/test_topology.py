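"""Graph thresholding, metrics, null models, and AUC summaries."""

import numpy as np
import pytest

from bruteforce import (
    bf_betweenness,
    bf_clustering,
    bf_eglob,
    bf_eloc,
    bf_lp,
    bf_nodal_efficiency,
    random_adj,
)
from morphconn import (
    BinaryGraph,
    ThresholdScheme,
    global_metrics,
    metric_auc,
    nodal_metrics,
    rewire_null,
    threshold_by_sparsity,
)


def _graph(adj):
    return BinaryGraph(adjacency=np.asarray(adj, dtype=bool))


def _random_weights(rng, n):
    w = rng.random((n, n))
    w = np.triu(w, 1)
    w = w + w.T
    np.fill_diagonal(w, 1.0)
    return w


class TestThresholdScheme:
    def test_default_has_25_thresholds(self):
        s = ThresholdScheme()
        assert len(s) == 25
        assert s.s_values[0] == pytest.approx(0.10)
        assert s.s_values[-1] == pytest.approx(0.34)

    @pytest.mark.parametrize("bad", [(0.2, 0.1), (0.0, 0.2), (0.5, 1.0)])
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(ValueError):
            ThresholdScheme(s_values=bad)


class TestThresholdBySparsity:
    def test_edge_count_round_half_up(self):
        rng = np.random.default_rng(0)
        w = _random_weights(rng, 90)
        assert threshold_by_sparsity(w, 0.10).n_edges == 401  # round-half-up(400.5)
        assert threshold_by_sparsity(w, 0.30).n_edges == 1202  # round-half-up(1201.5)

    def test_saturation_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        w = _random_weights(rng, 12)
        g = threshold_by_sparsity(w, 0.999)
        assert g.n_edges == 66
        assert np.all(g.adjacency[~np.eye(12, dtype=bool)])

    def test_strongest_edges_retained_vs_sort_oracle(self):
        rng = np.random.default_rng(2)
        n = 20
        w = _random_weights(rng, n)
        iu = np.triu_indices(n, k=1)
        planted = [(0, 5), (1, 7), (2, 9), (3, 11), (4, 13), (6, 15), (8, 17), (10, 19), (12, 14), (16, 18)]
        for i, j in planted:
            w[i, j] = w[j, i] = 2.0  # strictly above everything else
        m = iu[0].size
        s = 10 / m  # round-half-up(s*m) == 10
        g = threshold_by_sparsity(w, s)
        assert g.n_edges == 10
        assert all(g.adjacency[i, j] for i, j in planted)

    def test_deterministic_tie_breaking(self):
        n = 8
        w = np.ones((n, n))  # all ties: lexicographically first pairs win
        g = threshold_by_sparsity(w, 0.25)  # round_half_up(0.25*28) = 7
        iu = np.triu_indices(n, k=1)
        got = [(i, j) for i, j in zip(*iu) if g.adjacency[i, j]]
        assert got == [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6), (0, 7)]

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2])
    def test_sparsity_out_of_range(self, s):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_by_sparsity(np.eye(5), s)


class TestGlobalMetrics:
    def test_complete_graph_closed_form(self):
        adj = ~np.eye(5, dtype=bool)
        gm = global_metrics(_graph(adj), n_nulls=0)
        assert gm.cp == pytest.approx(1.0)
        assert gm.lp == pytest.approx(1.0)
        assert gm.eglob == pytest.approx(1.0)
        assert gm.eloc == pytest.approx(1.0)

    def test_path_graph_enumeration(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        gm = global_metrics(_graph(adj), n_nulls=0)
        assert gm.lp == pytest.approx(4 / 3)
        assert gm.cp == pytest.approx(0.0)

    def test_matches_brute_force_on_small_graphs(self):
        """All global and nodal measures equal exhaustive enumeration on
        100 random graphs of <= 8 nodes."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 9))
            adj = random_adj(rng, n, float(rng.uniform(0.25, 0.9)))
            if adj.sum() == 0:
                continue
            checked += 1
            g = _graph(adj)
            gm = global_metrics(g, n_nulls=0)
            nm = nodal_metrics(g)
            al = adj.tolist()
            assert gm.cp == pytest.approx(bf_clustering(al), abs=1e-12)
            assert gm.eglob == pytest.approx(bf_eglob(al), abs=1e-12)
            assert gm.eloc == pytest.approx(bf_eloc(al), abs=1e-12)
            lp = bf_lp(al)
            if np.isnan(lp):
                assert np.isnan(gm.lp)
            else:
                assert gm.lp == pytest.approx(lp, abs=1e-12)
            assert np.array_equal(nm.degree, adj.sum(axis=1))
            np.testing.assert_allclose(nm.efficiency, bf_nodal_efficiency(al), atol=1e-12)
            np.testing.assert_allclose(nm.betweenness, bf_betweenness(al), atol=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        adj = random_adj(rng, 25, 0.2)
        perm = rng.permutation(25)
        a = global_metrics(_graph(adj), n_nulls=0)
        b = global_metrics(_graph(adj[np.ix_(perm, perm)]), n_nulls=0)
        for attr in ("cp", "lp", "eglob", "eloc"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)

    def test_adding_edge_never_decreases_eglob(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            adj = random_adj(rng, 15, 0.2)
            if adj.sum() == 0:
                continue
            before = global_metrics(_graph(adj), n_nulls=0).eglob
            absent = np.argwhere(np.triu(~adj, 1))
            i, j = absent[rng.integers(len(absent))]
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = True
            assert global_metrics(_graph(adj2), n_nulls=0).eglob >= before - 1e-12

    def test_self_null_sigma_near_one(self):
        """A graph from the rewired ensemble of itself has sigma ~ 1."""
        rng = np.random.default_rng(6)
        adj = random_adj(rng, 60, 0.15)
        g = rewire_null(_graph(adj), seed=99)  # a draw from the null family
        gm = global_metrics(g, n_nulls=100, seed=7)
        assert gm.sigma == pytest.approx(1.0, abs=0.1)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            global_metrics(_graph(np.zeros((4, 4), dtype=bool)), n_nulls=0)


class TestNodalMetrics:
    def test_star_graph(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        nm = nodal_metrics(_graph(adj))
        assert nm.betweenness[0] == pytest.approx(6.0)
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)
        assert nm.efficiency[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.efficiency[1:], 0.625)
        assert nm.degree.sum() == 2 * 4

    def test_complete_graph_degrees(self):
        adj = ~np.eye(7, dtype=bool)
        nm = nodal_metrics(_graph(adj))
        assert np.all(nm.degree == 6)


class TestRewireNull:
    def test_preserves_degrees_and_edges(self):
        rng = np.random.default_rng(7)
        adj = random_adj(rng, 30, 0.2)
        g = _graph(adj)
        null = rewire_null(g, seed=1)
        assert null.n_edges == g.n_edges
        np.testing.assert_array_equal(
            null.adjacency.sum(axis=1), g.adjacency.sum(axis=1)
        )

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(8)
        g = _graph(random_adj(rng, 20, 0.3))
        a = rewire_null(g, seed=5).adjacency
        b = rewire_null(g, seed=5).adjacency
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, rewire_null(g, seed=6).adjacency)

    def test_ring_lattice_clustering_drops_to_random_level(self):
        n, k = 40, 4  # ring lattice, each node linked to k nearest
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                adj[i, (i + d) % n] = adj[(i + d) % n, i] = True
        g = _graph(adj)
        cp0 = global_metrics(g, n_nulls=0).cp
        cps = [global_metrics(rewire_null(g, seed=s), n_nulls=0).cp for s in range(10)]
        density = 2 * g.n_edges / (n * (n - 1))
        assert cp0 > 0.4
        assert np.mean(cps) < cp0 / 2
        assert np.mean(cps) == pytest.approx(density, abs=0.08)

    def test_too_small_to_swap(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.raises(ValueError, match="too small"):
            rewire_null(_graph(adj), seed=0)


class TestMetricAuc:
    def test_constant_curve(self):
        s = ThresholdScheme().array
        assert metric_auc(np.full(25, 2.0), s) == pytest.approx(0.48)

    def test_linear_ramp_trapezoid_oracle(self):
        s = ThresholdScheme().array
        v = np.linspace(0.0, 1.0, 25)
        manual = sum(
            (v[i] + v[i + 1]) / 2 * (s[i + 1] - s[i]) for i in range(24)
        )
        assert metric_auc(v, s) == pytest.approx(manual, abs=1e-15)
        assert metric_auc(v, s) == pytest.approx(0.12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two thresholds"):
            metric_auc([1.0], [0.2])
        with pytest.raises(ValueError, match="match"):
            metric_auc([1.0, 2.0], [0.1, 0.2, 0.3])
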