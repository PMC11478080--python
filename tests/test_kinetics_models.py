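"""Model functions, forward simulation and peak metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp, trapezoid
from scipy.optimize import brentq

from irmkin import (
    R,
    ConversionTrace,
    HeatingRamp,
    KineticProcess,
    f_alpha,
    peak_metrics,
    rate_constant,
    simulate_conversion,
    simulate_isothermal,
    synthesize_dsc,
)
from irmkin.kinetics_models import dsc_peak_area


class TestModelFunctions:
    @pytest.mark.parametrize(
        "proc,alpha,expected",
        [
            (KineticProcess("ac", E=1e5, lnA=10, M=0.0, N=1.0), 0.5, 0.5),
            (KineticProcess("jma", E=1e5, lnA=10, m=1.0), 0.5, 0.5),
            # 2·0.7·(−ln 0.7)^0.5, evaluated by hand
            (KineticProcess("jma", E=1e5, lnA=10, m=2.0), 0.3, 0.8361123188),
        ],
    )
    def test_f_alpha_values(self, proc, alpha, expected):
        assert f_alpha(proc, alpha) == pytest.approx(expected, abs=1e-6)

    def test_f_alpha_continuity_at_zero(self):
        proc = KineticProcess("jma", E=1e5, lnA=10, m=2.5)
        assert f_alpha(proc, 0.0) == 0.0

    def test_f_alpha_domain_error(self):
        proc = KineticProcess("jma", E=1e5, lnA=10, m=2.0)
        with pytest.raises(ValueError):
            f_alpha(proc, -0.1)
        with pytest.raises(ValueError):
            f_alpha(proc, 1.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticProcess("jma", E=1e5, lnA=10, m=0.0)
        with pytest.raises(ValueError):
            KineticProcess("jma", E=-1.0, lnA=10, m=2.0)
        with pytest.raises(ValueError):
            KineticProcess("ac", E=1e5, lnA=10, M=0.5, N=0.0)

    def test_rate_constant(self):
        assert rate_constant(0.0, 10.0, 500.0) == pytest.approx(np.e**10)
        # hand evaluation of exp(10 − 50000/(8.314·300))
        assert rate_constant(5e4, 10.0, 300.0) == pytest.approx(4.33e-5, rel=1e-2)
        assert rate_constant(5e4, 10.0, 310.0) > rate_constant(5e4, 10.0, 300.0)
        with pytest.raises(ValueError):
            rate_constant(5e4, 10.0, -3.0)


class TestSimulation:
    def test_jma_m1_equals_ac_first_order(self, study_ramp):
        jma = KineticProcess("jma", E=1e5, lnA=27.7, m=1.0)
        ac = KineticProcess("ac", E=1e5, lnA=27.7, M=0.0, N=1.0)
        a1 = simulate_conversion(jma, study_ramp).alpha
        a2 = simulate_conversion(ac, study_ramp).alpha
        assert np.max(np.abs(a1 - a2)) < 1e-8

    def test_quadrature_matches_ode_oracle(self, jma3_process, study_ramp):
        trace = simulate_conversion(jma3_process, study_ramp)
        # independent oracle: stiff integration of dα/dt = K·f(α) started
        # where the closed form reaches 1e-10
        i0 = int(np.searchsorted(trace.alpha, 1e-10))
        sol = solve_ivp(
            lambda t, a: [
                rate_constant(jma3_process.E, jma3_process.lnA, study_ramp.T_of_t(t))
                * f_alpha(jma3_process, min(a[0], 1.0 - 1e-15))
            ],
            (trace.t[i0], trace.t[-1]),
            [trace.alpha[i0]],
            t_eval=trace.t[i0:],
            method="LSODA",
            rtol=1e-10,
            atol=1e-13,
        )
        assert np.max(np.abs(sol.y[0] - trace.alpha[i0:])) < 1e-6

    def test_two_process_conservation(self, study_ramp):
        p1 = KineticProcess("jma", E=110e3, lnA=31.0, m=2.0, dh_frac=0.7)
        p2 = KineticProcess("jma", E=72e3, lnA=17.5, m=1.5, dh_frac=0.3)
        trace = simulate_conversion([p1, p2], study_ramp)
        assert trace.alpha[-1] == pytest.approx(1.0, abs=1e-6)
        # sub-process areas in the input enthalpy ratio
        areas = [
            p.dh_frac * trapezoid(
                rate_constant(p.E, p.lnA, trace.T) * f_alpha(p, a), trace.t
            )
            for p, a in zip(trace.processes, trace.per_process_alpha)
        ]
        assert areas[0] / areas[1] == pytest.approx(7.0 / 3.0, rel=1e-4)

    def test_dh_fracs_must_sum_to_one(self, study_ramp):
        p1 = KineticProcess("jma", E=110e3, lnA=31.0, m=2.0, dh_frac=0.7)
        p2 = KineticProcess("jma", E=72e3, lnA=17.5, m=1.5, dh_frac=0.2)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_conversion([p1, p2], study_ramp)

    def test_isothermal_first_order_closed_form(self):
        proc = KineticProcess("jma", E=5e4, lnA=10.0, m=1.0)
        t = np.linspace(0, 5e4, 200)
        K = rate_constant(5e4, 10.0, 330.0)
        assert simulate_isothermal(proc, 330.0, t) == pytest.approx(
            1 - np.exp(-K * t), abs=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        E=st.floats(5e4, 2e5),
        m=st.floats(0.5, 4.0),
        lnA_shift=st.floats(-3.0, 3.0),
    )
    def test_alpha_monotone_and_bounded(self, E, m, lnA_shift):
        # lnA tied loosely to E so some conversion happens inside the window
        lnA = E / (R * 360.0) - 6.0 + lnA_shift
        ramp = HeatingRamp.from_celsius(25.0, 150.0, 2.0)
        trace = simulate_conversion(KineticProcess("jma", E=E, lnA=lnA, m=m), ramp)
        assert np.all(np.diff(trace.alpha) >= -1e-12)
        assert trace.alpha.max() <= 1.0 + 1e-9
        assert np.all(trace.rate >= 0)


class TestDSC:
    def test_zero_enthalpy_gives_baseline(self, jma3_trace):
        base = 0.01 * np.ones_like(jma3_trace.T)
        curve = synthesize_dsc(jma3_trace, 0.0, base)
        assert np.array_equal(curve.phi, base)

    def test_peak_area_conservation(self, jma3_trace):
        curve = synthesize_dsc(jma3_trace, 60.0)
        assert dsc_peak_area(curve) == pytest.approx(60.0, rel=1e-3)


class TestPeakMetrics:
    def test_symmetric_gaussian_peak(self, study_ramp):
        t, T = np.linspace(0, study_ramp.duration, 20001), None
        T = study_ramp.T_of_t(t)
        rate = 1e-3 * np.exp(-0.5 * ((t - 3600.0) / 400.0) ** 2)
        alpha = np.clip(np.cumsum(rate) * (t[1] - t[0]), 0, 1)
        trace = ConversionTrace(
            t=t, T=T, alpha=alpha, rate=rate, ramp=study_ramp,
            processes=(KineticProcess("jma", E=1e5, lnA=10, m=1.0),),
        )
        pm = peak_metrics(trace)
        assert pm.asymmetry == pytest.approx(1.0, abs=0.01)
        assert pm.T_on5 < pm.T_p < pm.T_end5

    def test_first_order_stationarity_condition(self, fast_process, study_ramp):
        # at the rate maximum of a first-order peak, E·q⁺/(R·T_p²) = K(T_p)
        trace = simulate_conversion(fast_process, study_ramp)
        pm = peak_metrics(trace)
        E, lnA, q = fast_process.E, fast_process.lnA, study_ramp.q_K_s
        T_star = brentq(
            lambda T: E * q / (R * T**2) - rate_constant(E, lnA, T), 280.0, 400.0
        )
        assert abs(pm.T_p - T_star) < 0.05

    def test_width_shrinks_with_heating_rate(self, jma3_process):
        widths = []
        for q in (1.0, 10.0):
            ramp = HeatingRamp.from_celsius(25.0, 180.0, q)
            widths.append(peak_metrics(simulate_conversion(jma3_process, ramp)).width_t)
        assert widths[1] < widths[0]

    def test_truncated_peak_raises(self, fast_process):
        ramp = HeatingRamp.from_celsius(25.0, 45.0, 1.0)  # ends before T_p
        trace = simulate_conversion(fast_process, ramp)
        with pytest.raises(ValueError, match="truncated"):
            peak_metrics(trace)
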