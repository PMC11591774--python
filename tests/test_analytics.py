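"""Rescaling diagnostic, closed forms, alpha roots, slope and crossover."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import telediff as td
from telediff.analytics import (
    alpha_roots,
    asymptotic_slope,
    crossover_time,
    disk_diffusion_center,
    rescale_relaxation,
    wave_speed,
)


def trace_of(times, values):
    return td.CenterTrace(np.asarray(times, float), np.asarray(values, float))


class TestRescaleRelaxation:
    def test_known_points(self):
        tr = trace_of([0.0, 1.0], [1 - np.e**-1, 1 - np.e**-2])
        rt = rescale_relaxation(tr, C0=1.0)
        assert rt.values[0] == pytest.approx(1.0, rel=1e-14)
        assert rt.values[1] == pytest.approx(0.5, rel=1e-14)

    def test_masks_out_of_range_points(self):
        tr = trace_of([0, 1, 2, 3], [1.0, 0.5, 0.0, -0.1])
        rt = rescale_relaxation(tr, C0=1.0)
        assert list(rt.valid_mask) == [False, True, False, False]
        assert np.isnan(rt.values[~rt.valid_mask]).all()

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            rescale_relaxation(trace_of([0, 1], [1.0, 1.2]), C0=1.0)

    def test_closed_form_transform_is_exactly_linear(self, ic):
        # algebraic identity: -1/ln(1 - C(0,t)/C0) = (4 D / R^2) t.
        # Early samples are excluded: there 1 - C/C0 underflows towards the
        # float spacing at 1 and the inverse transform is ill-conditioned.
        D = 4e-5
        t = np.linspace(400.0, 2000.0, 300)
        tr = trace_of(t, disk_diffusion_center(t, D, ic))
        rt = rescale_relaxation(tr, C0=ic.C0)
        expected = (4 * D / ic.R**2) * t
        assert rt.valid_mask.all()
        assert np.max(np.abs(rt.values - expected)) < 1e-12


class TestDiskDiffusionCenter:
    def test_initial_value_and_e_folding(self, ic):
        D = 4e-5
        assert disk_diffusion_center(0.0, D, ic) == pytest.approx(ic.C0)
        t_star = ic.R**2 / (4 * D)
        assert disk_diffusion_center(t_star, D, ic) == pytest.approx(
            ic.C0 * (1 - np.e**-1), rel=1e-12
        )

    def test_reference_value_at_600s(self, ic):
        assert disk_diffusion_center(600.0, 4e-5, ic) == pytest.approx(0.99978, abs=1e-5)


class TestAlphaRoots:
    def test_zero_sink_roots(self):
        assert alpha_roots(td.TransportParams(1e-5, 1.0, 0.0)) == pytest.approx((0.0, 1.0))

    def test_reference_smaller_root_close_to_k(self):
        a1, _ = alpha_roots(td.TransportParams(4e-5, 1.0, 1.5e-4))
        assert a1 == pytest.approx(1.50023e-4, rel=1e-5)
        # the slow decay factor stays near unity over the full recording
        assert np.exp(-a1 * 600.0) > 0.9

    @given(tau=st.floats(0.01, 10.0), k=st.floats(0.0, 1e-2))
    def test_vieta_and_quadratic_residual(self, tau, k):
        p = td.TransportParams(1e-5, tau, k)
        if 4 * tau * k > 1:
            with pytest.raises(ValueError):
                alpha_roots(p)
            return
        a1, a2 = alpha_roots(p)
        assert a1 <= a2
        assert a1 + a2 == pytest.approx(1 / tau, rel=1e-10)
        assert a1 * a2 == pytest.approx(k / tau, abs=1e-12)
        for a in (a1, a2):
            assert abs(a * (tau * a - 1) + k) < 1e-12

    def test_requires_positive_tau(self):
        with pytest.raises(ValueError):
            alpha_roots(td.TransportParams(1e-5, 0.0, 1e-4))


class TestWaveSpeed:
    def test_reference_value(self):
        v = wave_speed(td.TransportParams(4e-5, 1.0, 1.5e-4))
        assert v == pytest.approx(6.32e-3, abs=1e-5)

    def test_scaling_and_degenerate_cases(self):
        assert wave_speed(td.TransportParams(0.0, 1.0, 0.0)) == 0.0
        assert wave_speed(td.TransportParams(4e-5, 4.0, 0.0)) == pytest.approx(3.16e-3, abs=1e-5)
        with pytest.raises(ValueError):
            wave_speed(td.TransportParams(4e-5, 0.0, 0.0))


class TestAsymptoticSlope:
    def test_recovers_exact_line(self):
        t = np.arange(0.0, 100.0)
        rt = td.RescaledTrace(t, 3e-4 * t + 0.02, np.ones(t.size, bool))
        slope, intercept = asymptotic_slope(rt, (10.0, 90.0))
        assert slope == pytest.approx(3e-4, rel=1e-12)
        assert intercept == pytest.approx(0.02, rel=1e-10)

    def test_pure_diffusion_slope_is_4D_over_R2(self, ic):
        D = 4e-5
        t = np.arange(1.0, 601.0)
        tr = trace_of(t, disk_diffusion_center(t, D, ic))
        rt = rescale_relaxation(tr, C0=ic.C0)
        slope, _ = asymptotic_slope(rt, (300.0, 600.0))
        assert slope == pytest.approx(4 * D / ic.R**2, rel=1e-6)

    def test_slope_stable_under_subsampling(self, ic):
        D = 4e-5
        t = np.arange(1.0, 601.0)
        tr = trace_of(t, disk_diffusion_center(t, D, ic))
        rt = rescale_relaxation(tr, C0=ic.C0)
        full, _ = asymptotic_slope(rt, (300.0, 600.0))
        sub = td.RescaledTrace(rt.times[::2], rt.values[::2], rt.valid_mask[::2])
        half, _ = asymptotic_slope(sub, (300.0, 600.0))
        assert half == pytest.approx(full, rel=1e-3)

    def test_too_few_points_raises(self):
        rt = td.RescaledTrace(np.arange(5.0), np.arange(5.0), np.ones(5, bool))
        with pytest.raises(ValueError):
            asymptotic_slope(rt, (10.0, 20.0))


class TestCrossoverTime:
    def test_exactly_linear_trace_crosses_at_first_sample(self):
        t = np.arange(0.0, 601.0)
        rt = td.RescaledTrace(t, 3e-4 * t + 0.05, np.ones(t.size, bool))
        res = crossover_time(rt, (3e-4, 0.05), tol=0.05)
        assert res.t_cross == t[0]

    def test_constructed_breakpoint_detected(self):
        rt = td.synth_breakpoint_trace(t_break=200.0, slope=3e-4, intercept=0.05,
                                       rel_offset=0.10)
        res = crossover_time(rt, (3e-4, 0.05), tol=0.05)
        assert abs(res.t_cross - 200.0) <= 1.0

    def test_quadratic_pre_segment_detected(self):
        rt = td.synth_breakpoint_trace(t_break=200.0, slope=3e-4, intercept=0.05,
                                       rel_offset=0.2, shape="quadratic")
        res = crossover_time(rt, (3e-4, 0.05), tol=0.05)
        assert abs(res.t_cross - 200.0) <= 1.0

    def test_sub_tolerance_offset_counts_as_settled(self):
        rt = td.synth_breakpoint_trace(t_break=200.0, slope=3e-4, intercept=0.05,
                                       rel_offset=0.02)
        res = crossover_time(rt, (3e-4, 0.05), tol=0.05)
        assert res.t_cross == rt.times[0]

    def test_never_settling_trace_raises(self):
        t = np.arange(0.0, 100.0)
        rt = td.RescaledTrace(t, 2.0 * (3e-4 * t + 0.05), np.ones(t.size, bool))
        with pytest.raises(ValueError, match="never settles"):
            crossover_time(rt, (3e-4, 0.05), tol=0.05)

    def test_simulated_reference_crossover_within_stage_one(self, sim2d_trace, ic):
        rt = rescale_relaxation(sim2d_trace, C0=ic.C0)
        res = td.crossover_from_trace(rt, window=(300.0, 600.0), tol=0.05)
        assert 100.0 <= res.t_cross <= 200.0


class TestMassOdeSolution:
    def test_matches_scipy_integration(self, ref_params):
        # independent oracle: integrate tau*M'' + M' + k*M = 0 numerically
        from scipy.integrate import solve_ivp

        p = ref_params
        t = np.linspace(0.0, 600.0, 61)
        rhs = lambda _t, y: [y[1], -(y[1] + p.k * y[0]) / p.tau]
        num = solve_ivp(rhs, (0, 600.0), [2.5, 0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.allclose(td.mass_ode_solution(t, p, 2.5), num.y[0], rtol=1e-6)
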