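"""sc-MKA weights, objective, parameter recovery and K(T) reconstruction."""

import numpy as np
import pytest
from dataclasses import replace

from irmkin import (
    R,
    HeatingRamp,
    KineticProcess,
    MKACurve,
    MKAProblem,
    SamplingScheme,
    correlation,
    curve_weight,
    compensation_and_K,
    delay_transform,
    fit_curve,
    fit_delayed_trace,
    objective,
    simulate_conversion,
)


class TestWeightAndCorrelation:
    @pytest.mark.parametrize(
        "series,expected",
        [([0.0, 1.0], 1.0), ([-0.5, 0.5], 1.0), ([0.0, 2e-3], 500.0)],
    )
    def test_curve_weight(self, series, expected):
        assert curve_weight(series) == pytest.approx(expected)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError):
            curve_weight([0.0, 0.0])

    def test_correlation_limits(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        r, log1mr = correlation(y, y)
        assert r == pytest.approx(1.0)
        assert log1mr == -16.0
        r, _ = correlation(y, -y)
        assert r == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            correlation(np.ones(5), y[:5])


class TestObjective:
    def test_truth_parameters_give_null_rss(self, jma3_process, study_ramp, jma3_trace):
        curve = MKACurve(
            t=jma3_trace.t, T=jma3_trace.T, y=jma3_trace.rate, ramp=study_ramp
        )
        problem = MKAProblem([curve], (jma3_process,))
        rss = objective(problem, (jma3_process,))
        assert rss < 1e-12 * curve.weight * float(jma3_trace.rate @ jma3_trace.rate)

    def test_single_point_residual_by_hand(self, jma3_process, study_ramp, jma3_trace):
        k = int(np.argmax(jma3_trace.rate))
        sl = slice(k - 1, k + 2)
        y = jma3_trace.rate[sl] + 1e-5
        curve = MKACurve(t=jma3_trace.t[sl], T=jma3_trace.T[sl], y=y, ramp=study_ramp,
                         model_t=jma3_trace.t, model_T=jma3_trace.T)
        problem = MKAProblem([curve], (jma3_process,))
        w = curve_weight(y)
        assert objective(problem, (jma3_process,)) == pytest.approx(
            w * 3 * (1e-5) ** 2, rel=1e-6
        )


class TestFitRecovery:
    def test_delayed_jma_refit_recovers_truth_in_zero_delay_limit(
        self, jma3_process, jma3_trace
    ):
        delayed = delay_transform(jma3_trace, SamplingScheme(t_s=10.0))
        fit = fit_delayed_trace(delayed, jma3_process)
        assert fit.status == "converged"
        assert fit.processes[0].m == pytest.approx(3.0, abs=5e-3)
        assert fit.processes[0].lnA == pytest.approx(10.0, abs=0.01)
        assert fit.r > 0.999

    def test_ac_parameter_recovery_noise_free(self):
        truth = KineticProcess("ac", E=1e5, lnA=27.7, M=0.5, N=1.2)
        ramp = HeatingRamp.from_celsius(50.0, 110.0, 1.0)
        trace = simulate_conversion(truth, ramp, dT=0.02)
        sl = slice(0, trace.t.size, 10)  # 300-point fitting grid
        curve = MKACurve(t=trace.t[sl], T=trace.T[sl], y=trace.rate[sl], ramp=ramp)
        start = replace(truth, lnA=26.5, M=0.8, N=0.8)
        fit = fit_curve(MKAProblem([curve], (start,)), multistart=False)
        assert fit.processes[0].lnA == pytest.approx(27.7, rel=0.01)
        assert fit.processes[0].M == pytest.approx(0.5, rel=0.01)
        assert fit.processes[0].N == pytest.approx(1.2, rel=0.01)

    def test_two_process_fraction_recovery(self):
        p1 = KineticProcess("jma", E=110e3, lnA=31.0, m=2.0, dh_frac=0.8)
        p2 = KineticProcess("jma", E=160e3, lnA=47.0, m=1.5, dh_frac=0.2)
        ramp = HeatingRamp.from_celsius(25.0, 150.0, 1.0)
        trace = simulate_conversion([p1, p2], ramp)
        sl = slice(0, trace.t.size, 20)
        curve = MKACurve(t=trace.t[sl], T=trace.T[sl], y=trace.rate[sl], ramp=ramp)
        start = (
            replace(p1, lnA=30.0, m=1.5, dh_frac=0.5),
            replace(p2, lnA=48.0, m=2.5, dh_frac=0.5),
        )
        fit = fit_curve(MKAProblem([curve], start), multistart=False)
        fracs = sorted(p.dh_frac for p in fit.processes)
        assert fracs[0] == pytest.approx(0.2, abs=0.02)
        assert fracs[1] == pytest.approx(0.8, abs=0.02)


class TestCompensation:
    def test_constant_E_monotone_K(self):
        T_grid = np.linspace(320.0, 430.0, 200)
        res = compensation_and_K(
            [350.0, 370.0, 390.0], [25.0, 25.0, 25.0],
            lambda T: np.full_like(np.asarray(T, float), 1e5), T_grid,
        )
        assert res["T_K_max"] is None
        assert np.all(np.diff(res["K"]) > 0)

    def test_constructed_interior_maximum(self):
        # falling E(T) compensated by lnA(T) so that K peaks at T*
        T_star, E0, b = 380.0, 1e5, -800.0
        slope = b / (R * T_star) - E0 / (R * T_star**2)
        T_pts = np.array([340.0, 380.0, 420.0])
        lnA_pts = 25.0 + slope * (T_pts - T_star)
        E_of_T = lambda T: E0 + b * (np.asarray(T, float) - T_star)
        res = compensation_and_K(T_pts, lnA_pts, E_of_T, np.linspace(330.0, 430.0, 500))
        assert res["T_K_max"] == pytest.approx(T_star, abs=1.0)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            compensation_and_K([350.0], [25.0], lambda T: 1e5, np.linspace(300, 400, 10))
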