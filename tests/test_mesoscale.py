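import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from chrononet.mesoscale import (
    AllegianceMatrix,
    MultilayerPartition,
    allegiance_matrix,
    export_system_edges,
    grid_search_gamma_omega,
    multilayer_q,
    optimize_multilayer,
    recruitment_integration,
    system_allegiance,
    system_recruitment_integration,
)
from chrononet.parcellation import default_parcellation
from chrononet.synth import planted_layers


def rand_weighted(rng, n):
    w = np.abs(rng.normal(size=(n, n)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return w


class TestMultilayerQ:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_layer_omega_zero_reduces_to_single_slice(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        w = rand_weighted(rng, n)
        labels = rng.integers(0, 3, n)
        q_multi = multilayer_q([w], labels[None, :], gamma=1.0, omega=0.0)
        q_single = oracles.modularity_value(w, labels, gamma=1.0)
        assert q_multi == pytest.approx(q_single, abs=1e-12)

    def test_duplicated_layer_keeps_q(self):
        rng = np.random.default_rng(1)
        w = rand_weighted(rng, 8)
        labels = rng.integers(0, 2, 8)
        q1 = multilayer_q([w], labels[None, :], 1.0, 0.0)
        q2 = multilayer_q([w, w], np.tile(labels, (2, 1)), 1.0, 0.0)
        assert q2 == pytest.approx(q1, abs=1e-12)

    def test_all_one_community_zero(self):
        rng = np.random.default_rng(2)
        layers = [rand_weighted(rng, 6) for _ in range(3)]
        labels = np.zeros((3, 6), dtype=int)
        assert multilayer_q(layers, labels, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_weights_warn(self):
        w = rand_weighted(np.random.default_rng(3), 5)
        w[0, 1] = w[1, 0] = -0.5
        with pytest.warns(UserWarning, match="negative"):
            multilayer_q([w], np.zeros((1, 5), int), 1.0, 0.0)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            multilayer_q([rand_weighted(rng, 5), rand_weighted(rng, 6)],
                         np.zeros((2, 5), int), 1.0, 0.1)


class TestOptimizeMultilayer:
    def test_planted_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        pm = planted_layers(4, 40, 4, p_in=0.9, p_out=0.05, seed=5)
        part = optimize_multilayer(pm.layers, gamma=1.0, omega=0.1,
                                   seed=11, n_reps=10)
        for s in range(4):
            assert adjusted_rand_score(pm.true_labels[s], part.labels[s]) == 1.0

    def test_strong_coupling_locks_labels_across_layers(self):
        pm = planted_layers(3, 20, 2, p_in=0.8, p_out=0.1, seed=6)
        part = optimize_multilayer(pm.layers, gamma=1.0, omega=50.0,
                                   seed=0, n_reps=5)
        assert (part.labels == part.labels[0]).all()

    def test_deterministic_under_seed(self):
        pm = planted_layers(3, 15, 3, p_in=0.9, p_out=0.1, seed=7)
        p1 = optimize_multilayer(pm.layers, 1.0, 0.1, seed=3, n_reps=5)
        p2 = optimize_multilayer(pm.layers, 1.0, 0.1, seed=3, n_reps=5)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_reported_q_matches_formula(self):
        pm = planted_layers(3, 12, 2, p_in=0.9, p_out=0.1, seed=8)
        part = optimize_multilayer(pm.layers, gamma=1.1, omega=0.3,
                                   seed=1, n_reps=5)
        q_direct = multilayer_q(pm.layers, part.labels, 1.1, 0.3)
        assert part.q == pytest.approx(q_direct, abs=1e-10)


class TestGridSearch:
    def test_single_cell(self):
        pm = planted_layers(2, 12, 2, 0.9, 0.1, seed=9)
        res = grid_search_gamma_omega(pm.layers, [1.0], [0.2], seed=0, n_reps=3)
        assert (res.gamma, res.omega) == (1.0, 0.2)
        assert len(res.surface) == 1

    def test_grid_size_bookkeeping(self):
        pm = planted_layers(2, 10, 2, 0.9, 0.1, seed=10)
        res = grid_search_gamma_omega(pm.layers, [0.8, 1.0, 1.2], [0.0, 0.1],
                                      seed=0, n_reps=2)
        assert len(res.surface) == 6
        assert res.q == res.surface.q.max()

    def test_protocol_grid_has_441_cells(self):
        gamma = np.round(np.arange(0.5, 1.5001, 0.05), 10)
        omega = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        assert len(gamma) * len(omega) == 441

    def test_row_major_tie_break(self):
        # two identical layers of two cliques: many cells give identical Q
        pm = planted_layers(2, 8, 2, 1.0, 0.0, seed=0)
        res = grid_search_gamma_omega(pm.layers, [1.0, 1.0], [0.0], seed=0,
                                      n_reps=2)
        assert res.surface.iloc[0].q == res.q  # first cell wins the tie

    def test_empty_grid(self):
        pm = planted_layers(2, 8, 2, 1.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            grid_search_gamma_omega(pm.layers, [], [0.1], seed=0)


class TestAllegiance:
    def test_identical_labels_give_binary_entries(self):
        labels = np.tile(np.repeat([0, 1], 4), (5, 1))
        part = MultilayerPartition(labels, q=0.0, gamma=1, omega=0)
        p = allegiance_matrix(part).p
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_half_coassignment(self):
        labels = np.array([[0, 0, 1], [0, 1, 1]])
        part = MultilayerPartition(labels, q=0.0, gamma=1, omega=0)
        p = allegiance_matrix(part).p
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 2] == pytest.approx(0.5)
        assert p[0, 2] == pytest.approx(0.0)

    def test_symmetric_unit_diagonal_and_multiples(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 3, size=(4, 10))
        p = allegiance_matrix(
            MultilayerPartition(labels, 0.0, 1, 0)).p
        np.testing.assert_allclose(p, p.T)
        np.testing.assert_allclose(np.diag(p), 1.0)
        np.testing.assert_allclose((p * 4) % 1, 0.0, atol=1e-12)


class TestRecruitmentIntegration:
    def test_block_allegiance_extremes(self, parc12):
        sysidx = parc12.system_of()
        p = (sysidx[:, None] == sysidx[None, :]).astype(float)
        am = AllegianceMatrix(p, n_layers=4)
        ri = recruitment_integration(am, parc12)
        np.testing.assert_allclose(ri.recruitment, 1.0)
        np.testing.assert_allclose(ri.integration, 0.0)

    def test_worked_example_0625(self):
        parc = default_parcellation(8, [("A", 4), ("B", 4)])
        p = np.zeros((8, 8))
        p[:4, :4] = 0.5
        np.fill_diagonal(p, 1.0)
        am = AllegianceMatrix(p, n_layers=2)
        ri = recruitment_integration(am, parc)
        np.testing.assert_allclose(ri.recruitment[:4], (1 + 3 * 0.5) / 4)

    def test_uniform_offdiagonal_gives_constant_integration(self, parc12):
        c = 0.3
        p = np.full((12, 12), c)
        np.fill_diagonal(p, 1.0)
        ri = recruitment_integration(AllegianceMatrix(p, 2), parc12)
        np.testing.assert_allclose(ri.integration, c, atol=1e-12)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_weighted_mean_identity(self, seed):
        parc = default_parcellation(12, [("A", 4), ("B", 4), ("C", 4)])
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, size=(6, 12))
        am = allegiance_matrix(MultilayerPartition(labels, 0.0, 1, 0))
        ri = recruitment_integration(am, parc)
        n = 12
        ns = np.array([4, 4, 4])[parc.system_of()]
        combo = (ns * ri.recruitment + (n - ns) * ri.integration) / n
        np.testing.assert_allclose(combo, am.p.mean(axis=1), atol=1e-12)
        assert ri.recruitment.between(0, 1).all()
        assert ri.integration.between(0, 1).all()


class TestSystemAllegiance:
    def test_block_constant_input(self, parc12):
        sysidx = parc12.system_of()
        vals = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.3], [0.1, 0.3, 1.0]])
        p = vals[np.ix_(sysidx, sysidx)].copy()
        np.fill_diagonal(p, 1.0)
        sm = system_allegiance(AllegianceMatrix(p, 4), parc12)
        # off-diagonal blocks reproduce the constants exactly
        assert sm.p[0, 1] == pytest.approx(0.2)
        assert sm.p[0, 2] == pytest.approx(0.1)
        assert sm.p[1, 2] == pytest.approx(0.3)
        # diagonal excludes self-pairs, so the unit diagonal does not inflate
        assert sm.p[0, 0] == pytest.approx(1.0)

    def test_hemisphere_pooling(self):
        # one system split across hemispheres with different block levels
        parc = default_parcellation(8, [("A", 2), ("B", 2)])  # mirrored 2+2
        p = np.full((8, 8), 0.0)
        sysidx = parc.system_of()
        amask = np.ix_(sysidx == 0, sysidx == 0)
        # LH_A pairs at 0.4, RH_A pairs at 0.6, cross-hemisphere A pairs mixed
        p[amask] = 0.5
        p[0:2, 0:2] = 0.4
        p[4:6, 4:6] = 0.6
        p = np.triu(p, 1) + np.triu(p, 1).T
        np.fill_diagonal(p, 1.0)
        sm = system_allegiance(AllegianceMatrix(p, 2), parc, merge_hemispheres=True)
        # pooled mean over the 6 distinct A pairs: (0.4 + 0.6 + 4*0.5)/6
        assert sm.p[0, 0] == pytest.approx((0.4 + 0.6 + 4 * 0.5) / 6)
        sm14 = system_allegiance(AllegianceMatrix(p, 2), parc,
                                 merge_hemispheres=False)
        assert sm14.p.shape == (4, 4)

    def test_shape_symmetry_and_exports(self, parc12):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 3, size=(5, 12))
        am = allegiance_matrix(MultilayerPartition(labels, 0.0, 1, 0))
        sm = system_allegiance(am, parc12)
        assert sm.p.shape == (3, 3)
        np.testing.assert_allclose(sm.p, sm.p.T)
        ri = system_recruitment_integration(sm)
        assert list(ri.system) == sm.names
        edges = export_system_edges(sm)
        assert len(edges) == 3


def test_recruitment_dominates_integration_on_planted_structure(parc40):
    """Strong planted systems: every system more recruited than integrated."""
    from chrononet.connectome import correlation_matrix
    from chrononet.synth import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_per_group=4, n_regions=40,
                       systems=[(s, 10) for s in "ABCD"], t_points=150, seed=21)
    panels, _ = simulate_cohort(cfg)
    layers = [correlation_matrix(p) for p in panels if p.session == "morning"]
    part = optimize_multilayer(layers, gamma=0.8, omega=0.1, seed=2, n_reps=5)
    sm = system_allegiance(allegiance_matrix(part), parc40)
    for i in range(4):
        for j in range(4):
            if i != j:
                assert sm.p[i, i] >= sm.p[i, j]
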