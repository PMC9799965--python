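import numpy as np
import pytest

import oracles
from chrononet.connectome import BinaryNetwork
from chrononet.metrics import (
    assortativity,
    auc_over_thresholds,
    betweenness,
    characteristic_path_length,
    extra_centralities,
    global_metrics,
    local_metrics,
    modularity_single,
    nodal_clustering,
    nodal_efficiency,
    nodal_path_length,
    participation_coefficient,
    random_reference,
    small_worldness,
    synchronization,
)
from chrononet.parcellation import default_parcellation
from chrononet.synth import make_toy_graph


class TestClosedForms:
    def test_star_center(self):
        g = make_toy_graph("star", 5)
        assert betweenness(g)[0] == pytest.approx(1.0)
        assert nodal_clustering(g)[0] == 0.0

    def test_triangle_everything_one(self):
        g = make_toy_graph("complete", 3)
        np.testing.assert_allclose(nodal_clustering(g), 1.0)
        np.testing.assert_allclose(nodal_path_length(g), 1.0)
        np.testing.assert_allclose(nodal_efficiency(g), 1.0)

    def test_k4_globals(self):
        g = make_toy_graph("complete", 4)
        gm = global_metrics(g)
        assert gm.clustering == pytest.approx(1.0)
        assert gm.char_path_length == pytest.approx(1.0)
        assert gm.efficiency == pytest.approx(1.0)

    def test_cycle6(self):
        g = make_toy_graph("cycle", 6)
        gm = global_metrics(g)
        assert gm.char_path_length == pytest.approx(1.8)
        assert gm.efficiency == pytest.approx(2 / 3)

    def test_participation_split(self, parc12):
        # region 0 with 2 links in system A, 2 in system B
        a = np.zeros((12, 12), dtype=int)
        for j in (1, 2, 4, 5):
            a[0, j] = a[j, 0] = 1
        p = participation_coefficient(BinaryNetwork(a), parc12.system_of())
        assert p[0] == pytest.approx(0.5)
        # all links inside own system -> P = 0
        a2 = np.zeros((12, 12), dtype=int)
        for j in (1, 2, 3):
            a2[0, j] = a2[j, 0] = 1
        p2 = participation_coefficient(BinaryNetwork(a2), parc12.system_of())
        assert p2[0] == 0.0

    def test_star_assortativity(self):
        assert assortativity(make_toy_graph("star", 5)) == pytest.approx(-1.0)

    def test_regular_graph_assortativity_undefined(self):
        assert np.isnan(assortativity(make_toy_graph("complete", 4)))

    def test_synchronization_spectra(self):
        assert synchronization(make_toy_graph("complete", 5))[0] == pytest.approx(1.0)
        s, lam2, lmax = synchronization(make_toy_graph("path", 3))
        assert (s, lam2, lmax) == (pytest.approx(1 / 3), pytest.approx(1.0),
                                   pytest.approx(3.0))
        two_edges = np.zeros((4, 4), dtype=int)
        two_edges[0, 1] = two_edges[1, 0] = two_edges[2, 3] = two_edges[3, 2] = 1
        assert synchronization(BinaryNetwork(two_edges))[0] == 0.0

    def test_isolated_node_conventions(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1  # node 3 isolated
        net = BinaryNetwork(a)
        li = nodal_path_length(net)
        assert np.isnan(li[3])
        assert characteristic_path_length(net) == pytest.approx(
            np.nanmean(li))
        assert nodal_efficiency(net)[3] == 0.0


class TestOracleEquivalence:
    """Fast metrics must match literal brute-force implementations."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_on_random_small_graphs(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 9))
        a = oracles.random_connected_graph(r, n, p=float(r.uniform(0.3, 0.8)))
        net = BinaryNetwork(a)
        parc = default_parcellation(n, [("A", n // 2), ("B", n - n // 2)])
        modules = parc.system_of()
        np.testing.assert_allclose(
            nodal_path_length(net), oracles.nodal_path_length(a), atol=1e-10)
        np.testing.assert_allclose(
            nodal_efficiency(net), oracles.nodal_efficiency(a), atol=1e-10)
        np.testing.assert_allclose(
            nodal_clustering(net), oracles.clustering(a), atol=1e-10)
        np.testing.assert_allclose(
            betweenness(net), oracles.betweenness(a), atol=1e-10)
        np.testing.assert_allclose(
            participation_coefficient(net, modules),
            oracles.participation(a, modules), atol=1e-10)
        ours, theirs = assortativity(net), oracles.assortativity(a)
        if np.isnan(theirs):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(theirs, abs=1e-10)
        assert synchronization(net)[0] == pytest.approx(
            oracles.synchronization(a), abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_modularity_reaches_exhaustive_maximum(self, seed):
        r = np.random.default_rng(100 + seed)
        n = int(r.integers(4, 8))
        a = oracles.random_connected_graph(r, n, 0.5)
        q, labels = modularity_single(BinaryNetwork(a), gamma=1.0,
                                      seed=seed, n_reps=30)
        q_best = oracles.max_modularity(a.astype(float), 1.0)
        assert q == pytest.approx(q_best, abs=1e-10)
        # reported q must equal the formula value of the reported labels
        assert q == pytest.approx(
            oracles.modularity_value(a.astype(float), labels), abs=1e-10)

    def test_degree_conservation(self):
        r = np.random.default_rng(5)
        a = oracles.random_connected_graph(r, 8, 0.5)
        net = BinaryNetwork(a)
        assert net.degrees().sum() == 2 * net.n_edges


class TestModularityExamples:
    def test_two_cliques_natural_partition(self):
        q, labels = modularity_single(make_toy_graph("two_cliques", 6),
                                      seed=0, n_reps=10)
        assert q == pytest.approx(0.5)
        assert len(np.unique(labels)) == 2

    def test_single_community_zero(self):
        g = make_toy_graph("planted_partition", 12, seed=1, n_communities=2)
        assert oracles.modularity_value(
            g.a.astype(float), np.zeros(12, int)) == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        g = make_toy_graph("planted_partition", 30, seed=3,
                           n_communities=2, p_in=0.9, p_out=0.05)
        _, labels = modularity_single(g, seed=0, n_reps=10)
        truth = np.repeat([0, 1], 15)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_agrees_with_leidenalg_quality(self):
        """Independent cross-check: our optimum is at least as good as the
        partition found by leidenalg's RBConfiguration optimizer."""
        import igraph as ig
        import leidenalg

        r = np.random.default_rng(8)
        a = oracles.random_connected_graph(r, 20, 0.25)
        g = ig.Graph.Adjacency((a > 0).tolist(), mode="undirected")
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, seed=1,
            resolution_parameter=1.0)
        q_leiden = oracles.modularity_value(
            a.astype(float), np.array(part.membership))
        q_ours, _ = modularity_single(BinaryNetwork(a), seed=0, n_reps=20)
        assert q_ours >= q_leiden - 1e-10


class TestRandomReference:
    def test_degree_sequence_preserved(self):
        g = make_toy_graph("planted_partition", 30, seed=2,
                           n_communities=3, p_in=0.7, p_out=0.2)
        ref = random_reference(g, n_swaps_per_edge=10, seed=1)
        np.testing.assert_array_equal(np.sort(ref.degrees()),
                                      np.sort(g.degrees()))
        assert ref.n_edges == g.n_edges

    def test_zero_swaps_identity_and_determinism(self):
        g = make_toy_graph("ring_lattice", 12, k=2)
        np.testing.assert_array_equal(random_reference(g, 0, seed=0).a, g.a)
        r1 = random_reference(g, 10, seed=9)
        r2 = random_reference(g, 10, seed=9)
        np.testing.assert_array_equal(r1.a, r2.a)


class TestSmallWorldness:
    def test_self_null_gives_sigma_one(self):
        g = make_toy_graph("ring_lattice", 20, k=2)
        res = small_worldness(g, n_null=5, seed=0, n_swaps_per_edge=0)
        assert res.sigma == pytest.approx(1.0)

    def test_er_graph_sigma_near_one_and_lattice_above(self):
        r = np.random.default_rng(3)
        er = oracles.random_connected_graph(r, 100, 0.1)
        res_er = small_worldness(BinaryNetwork(er), n_null=10, seed=1)
        assert 0.7 < res_er.sigma < 1.4
        # ring lattice with a few shortcuts: strongly clustered, short paths
        ws = make_toy_graph("ring_lattice", 100, k=3).a.copy().astype(int)
        shortcuts = [(0, 50), (10, 60), (20, 80), (30, 90), (5, 70)]
        for i, j in shortcuts:
            ws[i, j] = ws[j, i] = 1
        res_ws = small_worldness(BinaryNetwork(ws), n_null=10, seed=2)
        assert res_ws.sigma > 1.5


class TestExtraCentralities:
    def test_k4_core_numbers(self):
        df = extra_centralities(make_toy_graph("complete", 4))
        assert (df.kcore == 3).all()

    def test_cycle_eigenvector_uniform(self):
        df = extra_centralities(make_toy_graph("cycle", 8))
        assert df.eigenvector.std() < 1e-8

    def test_star_pagerank_center_largest(self):
        df = extra_centralities(make_toy_graph("star", 7))
        assert df.pagerank.idxmax() == 0

    def test_disconnected_eigenvector_on_largest_component(self):
        a = np.zeros((6, 6), dtype=int)
        a[:4, :4] = 1 - np.eye(4, dtype=int)  # K4 plus an edge 4-5
        a[4, 5] = a[5, 4] = 1
        df = extra_centralities(BinaryNetwork(a))
        assert np.all(df.eigenvector[:4] > 0)
        assert np.all(df.eigenvector[4:] == 0)


class TestAUC:
    def test_constant_curve(self):
        grid = np.round(np.arange(1, 11) * 0.05, 2)
        assert auc_over_thresholds(grid, np.full(10, 3.0)) == pytest.approx(0.45 * 3)

    def test_linear_ramp(self):
        assert auc_over_thresholds([0, 1], [0, 1]) == pytest.approx(0.5)

    def test_matches_manual_trapezoid(self):
        r = np.random.default_rng(0)
        xs = np.sort(r.uniform(0, 1, 17))
        ys = r.normal(size=17)
        assert auc_over_thresholds(xs, ys) == pytest.approx(
            oracles.trapezoid(xs, ys), abs=1e-12)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_over_thresholds([0.1, 0.05], [1, 2])


def test_local_metrics_frame(parc12):
    g = make_toy_graph("planted_partition", 12, seed=0, n_communities=3)
    df = local_metrics(g, parc12)
    assert list(df.region_id) == list(range(1, 13))
    assert set(df.columns) >= {"degree", "path_length", "clustering",
                               "efficiency", "betweenness", "participation"}
    assert df.betweenness.between(0, 1).all()
    assert df.participation.between(0, 1).all()
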