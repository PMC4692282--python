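import numpy as np
import pytest

from osclineage import (Trajectory, corr_distance, cv_distance, find_peaks,
                        ks_compare, sister_correlation, summarize, tree_peaks)
from osclineage.stats import (CorrelationFunction, PeakSet,
                              amplitude_and_period_cv, pool_peaks)


def _sine(period=41.0, t_end=400.0, amp=1.0, noise_sd=0.0, seed=0):
    t = np.arange(0.0, t_end, 3.0)
    x = amp * (1 + np.sin(2 * np.pi * t / period))
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return Trajectory(t, x)


class TestFindPeaks:
    def test_sinusoid_intervals_within_grid_quantisation(self):
        ps = find_peaks(_sine())
        assert ps.intervals.size >= 7
        assert ps.intervals.min() >= 39.0
        assert ps.intervals.max() <= 42.0

    def test_constant_trajectory_has_no_peaks(self):
        t = np.arange(0.0, 100.0, 3.0)
        ps = find_peaks(Trajectory(t, np.full(t.size, 5.0)))
        assert ps.heights.size == 0

    def test_smoothing_suppresses_noise_peaks(self):
        clean = find_peaks(_sine())
        noisy = find_peaks(_sine(noise_sd=0.1, seed=4))  # SNR ~ 10
        assert noisy.heights.size == clean.heights.size

    def test_amplitude_is_raw_height_not_smoothed(self):
        # a spike on top of an oscillation peak must be reported at its raw
        # (unsmoothed) height
        t = np.arange(0.0, 200.0, 3.0)
        x = 1 + np.sin(2 * np.pi * t / 41.0)
        i_peak = 17  # t = 51 min, near a sine maximum
        x[i_peak] *= 1.5
        ps = find_peaks(Trajectory(t, x))
        assert np.any(np.isclose(ps.heights, x[i_peak]))


class TestCvComputation:
    def test_hand_computed_sample_cv(self):
        peaks = PeakSet(np.array([0, 40, 80, 120.0]),
                        np.array([1.0, 1.0, 3.0, 3.0]),
                        np.array([40.0, 40.0, 40.0]))
        amp_cv, per_cv = amplitude_and_period_cv(peaks)
        # sample SD (n-1): sd([1,1,3,3]) = 1.1547, mean 2
        assert amp_cv == pytest.approx(1.1547 / 2, abs=1e-4)
        assert per_cv == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_amplitudes_give_zero_cv(self):
        peaks = PeakSet(np.array([0, 40, 80.0]), np.full(3, 2.0),
                        np.array([40.0, 40.0]))
        assert amplitude_and_period_cv(peaks)[0] == 0.0

    def test_scale_invariance_of_cv(self, sine_trees):
        s1 = summarize(sine_trees)
        scaled = []
        for tree in sine_trees:
            df = tree.to_frame()
            df["fluorescence"] *= 7.3
            from osclineage.lineage import LineageTree

            scaled.append(LineageTree.from_frame(df))
        s2 = summarize(scaled)
        assert s2.amplitude_cv == pytest.approx(s1.amplitude_cv, rel=1e-9)
        assert s2.period_cv == pytest.approx(s1.period_cv, rel=1e-9)

    def test_missed_beat_intervals_censored(self):
        # one doubled interval from a skipped peak must not inflate the CV
        intervals = np.array([40.0] * 20 + [80.0])
        heights = np.ones(intervals.size + 1)
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        _, per_cv = amplitude_and_period_cv(PeakSet(times, heights, intervals))
        assert per_cv == pytest.approx(0.0, abs=1e-12)

    def test_pooled_and_per_lineage_cvs_agree_on_homogeneous_data(self,
                                                                  sine_trees):
        pooled = summarize(sine_trees).amplitude_cv
        per = [summarize([t]).amplitude_cv for t in sine_trees]
        assert abs(np.mean(per) - pooled) < 0.1


class TestTreePeaks:
    def test_shared_history_not_double_counted(self, sine_trees):
        tree = sine_trees[0]
        pooled = tree_peaks(tree, transient_min=0.0)
        # peaks on the root cell appear in every root-to-leaf path but must
        # be counted once: peak count is far below n_paths * per-path count
        root = tree.nodes[tree.root_id]
        root_traj = Trajectory(root.frame_times, root.fluorescence)
        n_paths = len(tree.paths())
        n_root_peaks = find_peaks(root_traj).heights.size
        matches = np.sum(pooled.peak_times <= root.division_time)
        assert matches < n_paths * max(n_root_peaks, 1)

    def test_transient_exclusion(self, sine_trees):
        early = tree_peaks(sine_trees[0], transient_min=0.0)
        late = tree_peaks(sine_trees[0], transient_min=30.0)
        assert late.peak_times.min() >= 30.0
        assert late.heights.size <= early.heights.size


class TestSisterCorrelation:
    def test_identical_sisters_fully_correlated(self):
        # sisters with identical trajectories give rho = 1 wherever the
        # across-pair variance is positive
        from osclineage.lineage import LineageNode, LineageTree

        tree = LineageTree(0)
        t0 = np.arange(0.0, 30.0, 3.0)
        tree.add(LineageNode(0, None, 0, 0.0, 30.0, True, t0,
                             np.ones(t0.size)))
        t1 = np.arange(30.0, 60.0, 3.0)
        nid = 1
        for p, amp in [(0, 2.0), (0, 2.0)]:
            tree.add(LineageNode(nid, 0, 1, 30.0, 60.0, True, t1,
                                 amp * np.cos(t1 / 10.0)))
            nid += 1
        t2 = np.arange(60.0, 90.0, 3.0)
        for p in (1, 2):
            for amp in (3.0 + p,) * 2:  # identical within pair, distinct across
                tree.add(LineageNode(nid, p, 2, 60.0, 90.0, False, t2,
                                     amp * np.cos(t2 / 10.0)))
                nid += 1
        corr = sister_correlation(tree, max_lag=24.0)
        assert np.allclose(corr.rho[~np.isnan(corr.rho)], 1.0)

    def test_sine_fixture_sisters_correlated_then_decaying(self, sine_trees):
        corr = sister_correlation(sine_trees)
        assert corr.rho[0] > 0.5
        assert corr.rho[7] < corr.rho[0]  # lag 24 vs lag 3

    def test_independent_sisters_uncorrelated(self):
        from osclineage.lineage import LineageNode, LineageTree

        rng = np.random.default_rng(5)
        tree = LineageTree(0)
        t0 = np.arange(0.0, 30.0, 3.0)
        tree.add(LineageNode(0, None, 0, 0.0, 30.0, True, t0,
                             rng.normal(size=t0.size)))
        nid = 1
        for parent in [0]:
            pass
        # 40 independent-white-noise sister pairs under one root
        t1 = np.arange(30.0, 60.0, 3.0)
        tree2 = LineageTree(0)
        tree2.add(LineageNode(0, None, 0, 0.0, 30.0, True, t0,
                              rng.normal(size=t0.size)))
        # build a wide tree: root divides into 2, each divides again etc.
        frontier = [0]
        nid = 1
        birth = 30.0
        for gen in range(6):
            newf = []
            tgen = np.arange(birth, birth + 30.0, 3.0)
            for p in frontier:
                for _ in range(2):
                    tree2.add(LineageNode(nid, p, gen + 1, birth, birth + 30.0,
                                          gen < 5, tgen,
                                          rng.normal(size=tgen.size)))
                    newf.append(nid)
                    nid += 1
            frontier = newf
            birth += 30.0
        corr = sister_correlation(tree2)
        assert np.nanmax(np.abs(corr.rho)) < 0.5

    def test_lag_grid_starts_at_first_frame_after_division(self, sine_trees):
        corr = sister_correlation(sine_trees, max_lag=24.0)
        assert corr.lags[0] == 3.0
        assert corr.lags[-1] == 24.0


class TestDistances:
    def test_identical_inputs_give_zero(self):
        c = CorrelationFunction(np.arange(3.0, 33.0, 3.0), np.linspace(1, 0.5, 10),
                                np.full(10, 20))
        assert cv_distance(0.47, 0.47) == 0.0
        assert corr_distance(c, c) == 0.0

    def test_l2_distance_closed_form(self):
        lags = np.arange(3.0, 33.0, 3.0)
        a = CorrelationFunction(lags, np.linspace(1, 0.5, 10), np.full(10, 20))
        b = CorrelationFunction(lags, a.rho + 0.1, a.n_pairs)
        assert corr_distance(a, b) == pytest.approx(0.1 * np.sqrt(10))

    def test_absolute_cv_difference(self):
        assert cv_distance(0.35, 0.47) == pytest.approx(0.12)

    def test_disjoint_lag_grids_rejected(self):
        a = CorrelationFunction(np.array([3.0, 6.0]), np.array([1.0, 0.9]),
                                np.array([5, 5]))
        b = CorrelationFunction(np.array([9.0, 12.0]), np.array([1.0, 0.9]),
                                np.array([5, 5]))
        with pytest.raises(ValueError):
            corr_distance(a, b)


class TestKsCompare:
    def test_sample_against_itself(self):
        x = np.random.default_rng(0).normal(1, 0.47, 300)
        stat, p = ks_compare(x, x)
        assert stat == 0.0

    def test_null_distribution_pass_rate(self):
        """Same-law samples must pass at 95% confidence in >= 90% of seeds."""
        rng = np.random.default_rng(1)
        passes = 0
        n_rep = 40
        for _ in range(n_rep):
            a = rng.normal(1, 0.47, 300)
            b = rng.normal(1, 0.47, 300)
            _, p = ks_compare(a, b)
            passes += p > 0.05
        assert passes >= 0.9 * n_rep

    def test_mean_rescaling_removes_scale_differences(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1, 0.3, 400)
        _, p = ks_compare(a, 10.0 * a)
        assert p > 0.99  # identical after mean rescaling

    def test_different_shapes_detected(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.normal(1, 0.2, 500))
        b = rng.gamma(1.0, 1.0, 500)
        _, p = ks_compare(a, b)
        assert p < 0.05

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.ones(5), np.ones(50))
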