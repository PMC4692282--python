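import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osclineage import (IntegrationError, OscillatorParams, Trajectory,
                        fit_error, fit_parameters, hill_activity,
                        integrate_dde, measure_period, normalize_and_average,
                        rescale_params)
from osclineage.model_core import calibrate_repression_threshold


class TestHillActivity:
    def test_basal_activity_at_zero_inputs(self):
        assert hill_activity(0.0, 0.0, f=17.0) == pytest.approx(1 / 17)

    def test_saturation_at_high_activator(self):
        assert hill_activity(0.0, 1e9, f=17.0) == pytest.approx(1.0, abs=1e-6)

    def test_half_max_point_hand_value(self):
        # r = C_r, a = C_a: (1/f + 1) / (2 * 4)
        val = hill_activity(3.36, 0.791, f=17.0, C_a=0.791, C_r=3.36)
        assert val == pytest.approx((1 / 17 + 1) / 8, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_activity(-0.1, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(r=st.floats(0, 1e3), a=st.floats(0, 1e3))
    def test_bounded_between_zero_and_one(self, r, a):
        # basal floor 1/f > 0 at r=0; repression only lowers activity
        assert 0.0 < hill_activity(r, a) <= 1.0 + 1e-12


class TestRescaleParams:
    def test_identity_at_omega_one(self, params):
        assert rescale_params(params, 1.0) == params

    def test_elementwise_scaling(self, params):
        p2 = rescale_params(params, 2.0)
        assert p2.alpha_g == pytest.approx(2 * params.alpha_g)
        assert p2.gamma_r == pytest.approx(16.0)
        assert p2.R0 == pytest.approx(0.0912)
        assert p2.C_r == pytest.approx(6.72)
        # shape-determining and kinetic-timescale parameters untouched
        assert p2.f == params.f
        assert p2.tau_r == params.tau_r
        assert p2.lambda_mat == params.lambda_mat
        assert p2.beta == params.beta

    def test_nonpositive_omega_rejected(self, params):
        with pytest.raises(ValueError):
            rescale_params(params, 0.0)

    def test_scaling_equivalence_of_deterministic_family(self, params):
        """Trajectories of the rescaled system are omega times the original."""
        omega = 2.0
        hist = (0.0, 10.0, 0.0, 0.0)
        base = integrate_dde(params, history=hist, t_end=150.0, dt=0.01)
        scaled = integrate_dde(rescale_params(params, omega),
                               history=tuple(omega * h for h in hist),
                               t_end=150.0, dt=0.01)
        for col in ("r", "a", "g", "G"):
            ref = omega * base[col].to_numpy()
            got = scaled[col].to_numpy()
            assert np.allclose(got, ref, atol=1e-6 + 1e-6 * np.abs(ref).max())


class TestIntegrateDde:
    def test_zero_production_zero_history_stays_zero(self, params):
        dead = params.replace(alpha_r=0.0, alpha_a=0.0, alpha_g=0.0)
        sol = integrate_dde(dead, history=(0, 0, 0, 0), t_end=50.0, dt=0.01)
        assert np.allclose(sol[["r", "a", "g", "G"]].to_numpy(), 0.0, atol=0.0)

    def test_reference_parameters_oscillate_at_41_minutes(self, params):
        sol = integrate_dde(params, t_end=600.0)
        period = measure_period(sol)
        assert period == pytest.approx(41.0, abs=2.0)

    def test_solution_nonnegative(self, params):
        sol = integrate_dde(params, t_end=300.0)
        assert (sol[["r", "a", "g", "G"]].to_numpy() >= 0).all()

    def test_step_halving_self_convergence(self, params):
        # compare attractor observables at dt and dt/2: the sharp troughs
        # (near-zero total concentration) make pointwise early-time
        # comparison phase-sensitive, so period and amplitude are checked
        a = integrate_dde(params, t_end=600.0, dt=0.01)
        b = integrate_dde(params, t_end=600.0, dt=0.005)
        pa, pb = measure_period(a), measure_period(b)
        assert pa == pytest.approx(pb, rel=2e-3)
        ga = a["G"].to_numpy()[a["t"].to_numpy() > 300].max()
        gb = b["G"].to_numpy()[b["t"].to_numpy() > 300].max()
        assert ga == pytest.approx(gb, rel=5e-3)

    def test_dt_larger_than_delay_rejected(self, params):
        with pytest.raises(ValueError):
            integrate_dde(params, t_end=10.0, dt=10.0)

    def test_limit_cycle_robust_to_history_perturbation(self, params):
        p1 = measure_period(integrate_dde(params, history=(0, 10, 0, 0),
                                          t_end=600.0))
        p2 = measure_period(integrate_dde(params, history=(1, 12, 2, 1),
                                          t_end=600.0))
        assert p1 is not None and p2 is not None
        assert abs(p1 - p2) / p1 < 0.01


class TestNormalizeAndAverage:
    @staticmethod
    def _segment(scale=1.0, offset=0.0):
        t = np.arange(-33.0, 34.0, 3.0)
        vals = 0.5 * (1 + np.cos(2 * np.pi * t / 66.0))
        return Trajectory(t, scale * vals + offset)

    def test_single_normalized_segment_unchanged(self):
        seg = self._segment()
        out = normalize_and_average([seg])
        assert np.allclose(out.values, seg.values, atol=1e-12)

    def test_averaging_idempotent_on_copies(self):
        out1 = normalize_and_average([self._segment()])
        out2 = normalize_and_average([self._segment(), self._segment()])
        assert np.allclose(out1.values, out2.values)

    def test_scale_and_offset_invariance(self):
        out1 = normalize_and_average([self._segment()])
        out2 = normalize_and_average([self._segment(scale=5.0, offset=2.0)])
        assert np.allclose(out1.values, out2.values, atol=1e-12)

    def test_flat_segment_rejected(self):
        t = np.arange(-33.0, 34.0, 3.0)
        with pytest.raises(ValueError):
            normalize_and_average([Trajectory(t, np.ones_like(t))])

    def test_short_segment_rejected(self):
        t = np.arange(-15.0, 16.0, 3.0)
        with pytest.raises(ValueError):
            normalize_and_average([Trajectory(t, np.cos(t / 10.0))])


@pytest.fixture(scope="module")
def reference_oscillation(params):
    """Model-generated normalised reference oscillation + its period."""
    from osclineage.model_core import _simulated_reference_segment

    grid = np.arange(-33.0, 34.0, 3.0)
    seg, period = _simulated_reference_segment(params, grid, t_end=600.0,
                                               dt=0.05)
    return seg, period


class TestFitError:
    def test_zero_at_self_consistency(self, params, reference_oscillation):
        seg, period = reference_oscillation
        err = fit_error(params, seg, mu_per=period)
        assert err == pytest.approx(0.0, abs=1e-4)

    def test_pure_period_mismatch_term(self, params, reference_oscillation):
        seg, period = reference_oscillation
        # shape matches itself; target period half the simulated one gives
        # ((mu - sim) / mu)^2 = 1
        err = fit_error(params, seg, mu_per=period / 2.0)
        assert err == pytest.approx(1.0, abs=1e-3)

    def test_non_oscillating_parameters_flagged_infinite(self, params,
                                                         reference_oscillation):
        seg, period = reference_oscillation
        dead = params.replace(alpha_r=0.0, alpha_a=0.0, alpha_g=0.0)
        assert math.isinf(fit_error(dead, seg, mu_per=period))


class TestFitParameters:
    def test_empty_free_set_returns_start(self, params, reference_oscillation):
        seg, period = reference_oscillation
        res = fit_parameters(seg, period, p0=params, free=())
        assert res.params == params

    def test_error_never_worse_than_start(self, params, reference_oscillation):
        seg, period = reference_oscillation
        p0 = params.replace(C_r=params.C_r * 1.2)
        e0 = fit_error(p0, seg, mu_per=period)
        res = fit_parameters(seg, period, p0=p0, free=("C_r",), max_iter=8)
        assert res.error <= e0 + 1e-12

    def test_recovers_perturbed_parameter(self, params, reference_oscillation):
        # perturb repression threshold and activation strength by 20% and
        # refit both; the normalisation removes overall amplitude scale, so
        # identifiable shape parameters are the meaningful recovery check
        seg, period = reference_oscillation
        p0 = params.replace(C_r=params.C_r * 1.2, f=params.f * 1.2)
        e0 = fit_error(p0, seg, mu_per=period)
        res = fit_parameters(seg, period, p0=p0, free=("C_r", "f"),
                             max_iter=40)
        assert res.params.C_r == pytest.approx(params.C_r, rel=0.10)
        assert res.error < 0.1 * e0

    def test_unknown_free_name_rejected(self, params, reference_oscillation):
        seg, period = reference_oscillation
        with pytest.raises(ValueError):
            fit_parameters(seg, period, p0=params, free=("not_a_param",))


class TestRepressionCalibration:
    def test_reduces_cr_and_shortens_window_period(self, params):
        out = calibrate_repression_threshold(params, target_period=35.0,
                                             tol=1.0)
        assert out.C_r < params.C_r
        per = measure_period(integrate_dde(out, t_end=600.0))
        assert per is not None and per < 41.0

    def test_target_above_current_period_rejected(self, params):
        with pytest.raises(ValueError):
            calibrate_repression_threshold(params, target_period=60.0)
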