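import numpy as np
import pytest

from osclineage import (CellCycleParams, NoiseParams, Q_FIVE_GENERATIONS,
                        divide, resample_sister_params,
                        sample_division_volume, sample_growth_rate,
                        sample_stationary_param, simulate_lineage,
                        simulate_lineages, stationary_param_cv)
from osclineage.lineage import CellState, LineageTree


class TestGrowthRateSampling:
    def test_zero_variability_returns_mean(self):
        cc = CellCycleParams(gamma_beta=1e-12)
        rng = np.random.default_rng(0)
        assert sample_growth_rate(cc, rng) == pytest.approx(0.0295, rel=1e-6)

    def test_moments_match_population_statistics(self, cell_cycle):
        rng = np.random.default_rng(1)
        draws = np.array([sample_growth_rate(cell_cycle, rng)
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.0295, rel=0.01)
        assert draws.std() / draws.mean() == pytest.approx(0.099, rel=0.05)
        # symmetric about the mean
        med = np.median(draws)
        assert med == pytest.approx(draws.mean(), rel=0.01)


class TestDivisionVolumeSampling:
    def test_mean_is_base_plus_gamma_mean(self, cell_cycle):
        rng = np.random.default_rng(2)
        draws = np.array([sample_division_volume(cell_cycle, rng)
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(
            cell_cycle.v_base + cell_cycle.k_gamma * cell_cycle.theta_gamma,
            rel=0.02)
        assert (draws > cell_cycle.v_base).all()

    def test_truncation_respects_birth_volume(self, cell_cycle):
        rng = np.random.default_rng(3)
        draws = [sample_division_volume(cell_cycle, rng, min_volume=6.0)
                 for _ in range(2000)]
        assert min(draws) > 6.0


class TestParameterRecursion:
    def test_sisters_satisfy_mean_constraint_exactly(self):
        rng = np.random.default_rng(4)
        q, gamma, mean = Q_FIVE_GENERATIONS, 0.12, 100.0
        for p_mother in (80.0, 100.0, 130.0):
            p1, p2 = resample_sister_params(p_mother, mean, gamma, q, rng)
            m = q * p_mother + (1 - q) * mean
            assert 0.5 * (p1 + p2) == pytest.approx(m, rel=1e-12)

    def test_zero_variability_gives_reverted_mean(self):
        rng = np.random.default_rng(5)
        p1, p2 = resample_sister_params(80.0, 100.0, 0.0, 0.5, rng)
        assert p1 == p2 == pytest.approx(0.5 * 80 + 0.5 * 100)

    def test_full_memory_keeps_mother_value(self):
        rng = np.random.default_rng(6)
        p1, p2 = resample_sister_params(80.0, 100.0, 0.0, 1.0, rng)
        assert p1 == pytest.approx(80.0)

    def test_stationary_moments_match_variance_recursion(self):
        """Monte-Carlo chain vs the closed-form stationary CV.

        For p' = (q p + (1-q)<p>)(1 + G eta) the stationary mean is <p>
        and CV^2 = G^2 / (1 - q^2 (1 + G^2)).
        """
        q, gamma, mean = Q_FIVE_GENERATIONS, 0.12, 1.0
        rng = np.random.default_rng(7)
        p = mean
        chain = np.empty(100_000)
        for i in range(chain.size):
            p = (q * p + (1 - q) * mean) * (1 + gamma * rng.standard_normal())
            chain[i] = p
        chain = chain[1000:]
        assert chain.mean() == pytest.approx(mean, rel=0.02)
        assert chain.std() / chain.mean() == pytest.approx(
            stationary_param_cv(gamma, q), rel=0.07)

    def test_stationary_sampler_matches_analytic_cv(self):
        rng = np.random.default_rng(8)
        draws = np.array([
            sample_stationary_param(1.0, 0.12, Q_FIVE_GENERATIONS, rng)
            for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(1.0, rel=0.02)
        assert draws.std() / draws.mean() == pytest.approx(
            stationary_param_cv(0.12, Q_FIVE_GENERATIONS), rel=0.10)

    def test_divergent_regime_reported_infinite(self):
        assert stationary_param_cv(0.5, 0.95) == float("inf")


def _make_cell(counts, v=7.0, v_max=7.0, queues=None):
    if queues is None:
        queues = (np.array([10.0, 11.0]), np.array([12.0]), np.empty(0))
    return CellState(np.asarray(counts, dtype=np.int64), v, 100.0, queues,
                     131.25, 630.0, 1260.0, 0.0295, v_max)


class TestDivide:
    def test_molecule_and_queue_conservation(self, fitted_noise, cell_cycle):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cell = _make_cell([40, 200, 350, 120])
            d1, d2 = divide(cell, fitted_noise, cell_cycle,
                            (131.25, 630.0, 1260.0), rng)
            assert (d1.counts + d2.counts == cell.counts).all()
            for qa, qb, qm in zip(d1.queues, d2.queues, cell.queues):
                merged = np.sort(np.concatenate([qa, qb]))
                assert np.array_equal(merged, np.sort(qm))

    def test_volume_halved_and_fresh_cycle_parameters(self, fitted_noise,
                                                      cell_cycle):
        rng = np.random.default_rng(10)
        cell = _make_cell([10, 10, 10, 10])
        d1, d2 = divide(cell, fitted_noise, cell_cycle,
                        (131.25, 630.0, 1260.0), rng)
        assert d1.v == d2.v == pytest.approx(cell.v / 2)
        assert d1.v_max > d1.v and d2.v_max > d2.v

    def test_binomial_partition_symmetry(self, fitted_noise, cell_cycle):
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(400):
            cell = _make_cell([0, 0, 0, 300])
            d1, d2 = divide(cell, fitted_noise, cell_cycle,
                            (131.25, 630.0, 1260.0), rng)
            diffs.append(d1.counts[3] - d2.counts[3])
        diffs = np.asarray(diffs, dtype=float)
        # zero-mean and near-binomial spread (sd ~ sqrt(n))
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert diffs.std(ddof=1) == pytest.approx(np.sqrt(300), rel=0.2)

    def test_division_below_threshold_rejected(self, fitted_noise, cell_cycle):
        rng = np.random.default_rng(12)
        cell = _make_cell([1, 1, 1, 1], v=5.0, v_max=7.0)
        with pytest.raises(ValueError):
            divide(cell, fitted_noise, cell_cycle, (131.25, 630.0, 1260.0),
                   rng)


class TestSimulateLineage:
    def test_single_generation_gives_three_cells(self, params, fitted_noise,
                                                 init_cycle):
        tree = simulate_lineage(params, fitted_noise, n_generations=1,
                                seed=13, init_cycle=init_cycle)
        assert len(tree.nodes) == 3
        root = tree.nodes[tree.root_id]
        for cid in tree.children(tree.root_id):
            assert tree.nodes[cid].birth_time == pytest.approx(
                root.division_time)

    def test_tree_topology_zero_or_two_daughters(self, params, fitted_noise,
                                                 init_cycle):
        tree = simulate_lineage(params, fitted_noise, n_generations=3,
                                seed=14, init_cycle=init_cycle)
        assert len(tree.nodes) == 2 ** 4 - 1
        for cid in tree.nodes:
            assert len(tree.children(cid)) in (0, 2)

    def test_frames_on_global_grid(self, params, fitted_noise, init_cycle):
        tree = simulate_lineage(params, fitted_noise, n_generations=2,
                                seed=15, init_cycle=init_cycle)
        for node in tree.nodes.values():
            assert np.allclose(node.frame_times % 3.0, 0.0, atol=1e-9)
            assert (node.frame_times >= node.birth_time - 1e-9).all()
            assert (node.frame_times <= node.division_time + 1e-9).all()

    def test_movie_end_truncates_branches(self, params, fitted_noise,
                                          init_cycle):
        tree = simulate_lineage(params, fitted_noise, n_generations=50,
                                seed=16, t_max=90.0, init_cycle=init_cycle)
        assert max(n.division_time for n in tree.nodes.values()) <= 90.0 + 1e-9

    def test_sisters_nearly_identical_at_first_frame(self, params,
                                                     fitted_noise,
                                                     cell_cycle):
        from osclineage import sister_correlation

        trees = simulate_lineages(params, fitted_noise, cell_cycle,
                                  n_lineages=6, n_generations=5, seed=17)
        corr = sister_correlation(trees)
        assert corr.rho[0] > 0.9

    def test_extrinsic_noise_raises_amplitude_variability(self, params,
                                                          cell_cycle):
        from osclineage import summarize

        lo = summarize(simulate_lineages(
            params, NoiseParams(omega=1.0, gamma_ext=0.0), cell_cycle,
            n_lineages=10, n_generations=5, seed=18))
        hi = summarize(simulate_lineages(
            params, NoiseParams(omega=1.0, gamma_ext=0.15), cell_cycle,
            n_lineages=10, n_generations=5, seed=18))
        assert hi.amplitude_cv > lo.amplitude_cv

    def test_same_seed_reproduces_tree_exactly(self, params, fitted_noise,
                                               init_cycle):
        t1 = simulate_lineage(params, fitted_noise, n_generations=2, seed=19,
                              init_cycle=init_cycle)
        t2 = simulate_lineage(params, fitted_noise, n_generations=2, seed=19,
                              init_cycle=init_cycle)
        assert t1.to_frame().equals(t2.to_frame())


class TestLineageTreeContainer:
    def test_roundtrip_through_tidy_frame(self, sine_trees):
        tree = sine_trees[0]
        back = LineageTree.from_frame(tree.to_frame())
        assert set(back.nodes) == set(tree.nodes)
        for cid in tree.nodes:
            assert np.allclose(back.nodes[cid].fluorescence,
                               tree.nodes[cid].fluorescence)
            assert back.children(cid) == tree.children(cid) or \
                sorted(back.children(cid)) == sorted(tree.children(cid))

    def test_paths_cover_all_leaves(self, sine_trees):
        tree = sine_trees[0]
        leaves = {cid for cid in tree.nodes if not tree.children(cid)}
        paths = tree.paths()
        assert {p[-1] for p in paths} == leaves
        assert all(p[0] == tree.root_id for p in paths)

    def test_orphan_parent_rejected(self):
        from osclineage.lineage import LineageNode

        tree = LineageTree(0)
        with pytest.raises(ValueError):
            tree.add(LineageNode(5, 99, 1, 0.0, 10.0, False,
                                 np.array([0.0]), np.array([1.0])))
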