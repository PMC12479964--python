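"""Longevity/production metric tests: closed-form crossings, cumulative
output, and the equal-output open-loop comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import circuitevo as ce
from circuitevo.metrics import (NOT_REACHED, build_openloop_reference,
                                crossing_times, cumulative_output,
                                percent_change_vs_openloop, total_output)
from circuitevo.population import EvolutionTrace
from tests_helpers import synthetic_trace


class TestTotalOutput:
    def test_weighted_sum(self):
        assert total_output([10, 20], [5, 1]) == 70.0
        assert total_output([10, 20], [0, 0]) == 0.0

    def test_permutation_invariance(self):
        a = total_output([10, 20, 5], [1, 2, 3])
        b = total_output([5, 10, 20], [3, 1, 2])
        assert a == b

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            total_output([1, 2], [1])


class TestCrossingTimes:
    def test_linear_decline_closed_form(self):
        t = np.linspace(0, 100, 201)
        P0 = 8.0
        ct = crossing_times(t, P0 * (1 - t / 100.0))
        assert ct.tau_pm10 == pytest.approx(10.0)
        assert ct.tau_90 == pytest.approx(10.0)
        assert ct.tau_50 == pytest.approx(50.0)
        assert not ct.tau_split

    def test_rising_trace_exits_through_upper_bound(self):
        t = np.linspace(0, 100, 101)
        ct = crossing_times(t, 4.0 * (1 + t / 50.0))
        assert ct.tau_pm10 == pytest.approx(5.0)
        assert ct.upper_exit
        assert ct.tau_90 == NOT_REACHED
        assert ct.tau_50 == NOT_REACHED
        assert ct.tau_split

    def test_constant_trace_never_crosses(self):
        t = np.linspace(0, 10, 11)
        ct = crossing_times(t, np.full(11, 3.0))
        assert math.isinf(ct.tau_pm10)
        assert math.isinf(ct.tau_90)
        assert math.isinf(ct.tau_50)
        assert ct.P_max == 3.0

    @given(scale=st.floats(1e-3, 1e6))
    def test_scale_invariance(self, scale):
        t = np.linspace(0, 60, 61)
        P = 5.0 * np.exp(-t / 20.0)
        a = crossing_times(t, P)
        b = crossing_times(t, scale * P)
        assert a.tau_pm10 == pytest.approx(b.tau_pm10)
        assert a.tau_50 == pytest.approx(b.tau_50)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            crossing_times([0, 1], [1.0, 0.5], P0=0.0)
        with pytest.raises(ValueError):
            crossing_times([0, 0], [1.0, 1.0])


class TestCumulativeOutput:
    def test_constant_flux_rectangle(self):
        tr = synthetic_trace(np.linspace(0, 10, 11), N=1000.0, T_L_A=2.0)
        assert cumulative_output(tr) == pytest.approx(20000.0)

    def test_strain_additivity(self):
        t = np.linspace(0, 10, 11)
        one = synthetic_trace(t, N=1000.0, T_L_A=2.0)
        two = EvolutionTrace(
            t=t, N=np.full((11, 2), 500.0), s_X=np.zeros(11),
            p_A=np.ones((11, 2)), lam=np.zeros((11, 2)),
            T_L_A=np.full((11, 2), 2.0), P=np.full(11, 100.0),
            day_end_idx=np.arange(11), states=[(100,), (67,)])
        assert cumulative_output(two) == pytest.approx(cumulative_output(one))

    def test_stop_rule_truncates_integral(self):
        # output collapses below 1% of P0 at t = 5: production afterwards
        # does not count
        t = np.linspace(0, 10, 1001)
        P = np.where(t < 5.0, 100.0, 0.5)
        tr = synthetic_trace(t, N=1000.0, T_L_A=2.0, P=P)
        assert cumulative_output(tr) == pytest.approx(10000.0, rel=2e-3)

    def test_solver_channel_preferred(self):
        tr = synthetic_trace(np.linspace(0, 10, 11), N=1000.0, T_L_A=2.0)
        tr.Q_cum = np.linspace(0.0, 12345.0, 11)
        assert cumulative_output(tr) == pytest.approx(12345.0)


class TestOpenLoopReference:
    def test_linear_interpolation(self):
        ref = build_openloop_reference([1.0, 2.0, 3.0],
                                       [100.0, 80.0, 60.0],
                                       [200.0, 160.0, 120.0])
        assert ref.tau_pm10_at(2.5) == pytest.approx(70.0)
        assert ref.tau_50_at(2.5) == pytest.approx(140.0)

    def test_overburdened_branch_removed(self):
        # fold: P0 rises to 3 then falls back; retained branch is the
        # prefix up to the argmax
        P0 = [1.0, 2.0, 3.0, 2.5, 1.5]
        tau = [100.0, 80.0, 60.0, 50.0, 40.0]
        ref = build_openloop_reference(P0, tau, tau)
        np.testing.assert_allclose(ref.P0, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(ref.tau_50, [100.0, 80.0, 60.0])

    def test_no_extrapolation(self):
        ref = build_openloop_reference([1.0, 2.0], [10.0, 5.0], [20.0, 10.0])
        with pytest.raises(ValueError, match="outside"):
            ref.tau_50_at(5.0)

    def test_filtered_reference_non_increasing(self):
        # longevity falls as output rises on the retained branch
        rng = np.random.default_rng(3)
        omega = np.geomspace(0.1, 100, 30)
        P0 = omega / (1 + (omega / 40.0) ** 2)       # interior maximum
        tau = 100.0 / (1.0 + omega)
        ref = build_openloop_reference(P0, tau, tau)
        assert np.all(np.diff(ref.tau_50) <= 0)


class TestPercentChange:
    def test_self_comparison_is_zero(self):
        ref = build_openloop_reference([1.0, 3.0], [10.0, 6.0],
                                       [30.0, 20.0], Q=[5.0, 9.0])
        met = ce.DesignMetrics(P0=2.0, tau_pm10=8.0, tau_90=8.0,
                               tau_50=25.0, P_max=2.0, Q=7.0,
                               upper_exit=False)
        pc = percent_change_vs_openloop(met, ref)
        assert pc["tau_pm10"] == pytest.approx(0.0)
        assert pc["tau_50"] == pytest.approx(0.0)
        assert pc["Q"] == pytest.approx(0.0)

    def test_doubling_and_sign(self):
        ref = build_openloop_reference([1.0, 3.0], [10.0, 10.0],
                                       [20.0, 20.0])
        twice = ce.DesignMetrics(P0=2.0, tau_pm10=10.0, tau_90=10.0,
                                 tau_50=40.0, P_max=2.0, Q=0.0,
                                 upper_exit=False)
        worse = ce.DesignMetrics(P0=2.0, tau_pm10=5.0, tau_90=5.0,
                                 tau_50=10.0, P_max=2.0, Q=0.0,
                                 upper_exit=False)
        assert percent_change_vs_openloop(twice, ref)["tau_50"] == \
            pytest.approx(100.0)
        assert percent_change_vs_openloop(worse, ref)["tau_50"] == \
            pytest.approx(-50.0)
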