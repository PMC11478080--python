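"""Solid-state kinetic models and forward simulation under linear heating.

The module implements the Arrhenian rate equation for the crystallization of
an amorphous phase,

    dα/dt = A · exp(-E / R T) · f(α) = K(T) · f(α),

with the two model functions used throughout pharmaceutical solid-state
kinetics:

* the Johnson–Mehl–Avrami (JMA) nucleation-growth model,
  f(α) = m (1-α) (-ln(1-α))^(1-1/m), and
* the semi-empirical autocatalytic Šesták–Berggren (AC) model,
  f(α) = α^M (1-α)^N.

A crystallization exotherm measured by DSC is modelled as a sum of
independent sub-processes, each carrying a fraction ``dh_frac`` of the total
crystallization enthalpy.  Under a linear heating ramp T(t) = T_start + q⁺·t
the JMA solution has the closed form α = 1 - exp(-θ^m) with
θ(t) = ∫₀ᵗ K(T(s)) ds, which is used as the fast simulation route; AC
processes are integrated numerically.  Rates are always evaluated from the
analytic expression K(T)·f(α) rather than by differencing, so that fitted
quantities are free of differentiation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp, trapezoid

__all__ = [
    "R",
    "KineticProcess",
    "HeatingRamp",
    "ConversionTrace",
    "DSCCurve",
    "PeakMetrics",
    "f_alpha",
    "rate_constant",
    "simulate_conversion",
    "simulate_isothermal",
    "synthesize_dsc",
    "peak_metrics",
]

#: Universal gas constant, J·mol⁻¹·K⁻¹.
R = 8.314

#: Default seeding value for autocatalytic integrations (f_AC(0) = 0 for
#: M > 0, so the ODE must start from a small positive conversion).
AC_ALPHA0 = 1e-8

#: Default temperature step of the simulation grid, K.  Fine enough to
#: resolve the sharpest peaks studied here and to make acquisition-time
#: sampling an interpolation, not a grid-coincidence, problem.
DEFAULT_DT_K = 0.01


@dataclass(frozen=True)
class KineticProcess:
    """One crystallization sub-process.

    Parameters
    ----------
    model : {"jma", "ac"}
        Kinetic model kind.
    E : float
        Activation energy, J·mol⁻¹ (> 0).
    lnA : float
        Natural log of the pre-exponential factor, ln(s⁻¹).
    m : float, optional
        JMA kinetic exponent (JMA only), within [0.5, 4].
    M, N : float, optional
        Šesták–Berggren exponents (AC only); M ≥ 0, N > 0.
    dh_frac : float
        Fraction of the total crystallization enthalpy carried by this
        sub-process, in (0, 1].
    """

    model: Literal["jma", "ac"]
    E: float
    lnA: float
    m: float | None = None
    M: float | None = None
    N: float | None = None
    dh_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("jma", "ac"):
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if not self.E > 0:
            raise ValueError("activation energy E must be positive")
        if not 0.0 < self.dh_frac <= 1.0:
            raise ValueError("dh_frac must lie in (0, 1]")
        if self.model == "jma":
            if self.m is None:
                raise ValueError("JMA process requires exponent m")
            if not 0.5 <= self.m <= 4.0:
                raise ValueError("JMA exponent m must lie in [0.5, 4]")
        else:
            if self.M is None or self.N is None:
                raise ValueError("AC process requires exponents M and N")
            if self.M < 0:
                raise ValueError("AC exponent M must be >= 0")
            if not self.N > 0:
                raise ValueError("AC exponent N must be positive")


def _check_dh_fracs(processes: Sequence[KineticProcess]) -> None:
    total = sum(p.dh_frac for p in processes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"enthalpy fractions of a process set must sum to 1 (got {total})"
        )


@dataclass(frozen=True)
class HeatingRamp:
    """Linear heating program T(t) = T_start + q⁺·t.

    Temperatures are kelvin; the heating rate ``q_plus`` is stored in the
    conventional °C·min⁻¹ and converted to K·s⁻¹ internally.
    """

    T_start: float
    T_end: float
    q_plus: float  # °C·min⁻¹

    def __post_init__(self) -> None:
        if not self.T_end > self.T_start:
            raise ValueError("T_end must exceed T_start")
        if not self.q_plus > 0:
            raise ValueError("heating rate q_plus must be positive")

    @property
    def q_K_s(self) -> float:
        """Heating rate in K·s⁻¹."""
        return self.q_plus / 60.0

    @property
    def duration(self) -> float:
        """Total ramp time, s."""
        return (self.T_end - self.T_start) / self.q_K_s

    def T_of_t(self, t):
        return self.T_start + self.q_K_s * np.asarray(t)

    def t_of_T(self, T):
        return (np.asarray(T) - self.T_start) / self.q_K_s

    @classmethod
    def from_celsius(cls, T_start_C: float, T_end_C: float, q_plus: float) -> "HeatingRamp":
        return cls(T_start_C + 273.15, T_end_C + 273.15, q_plus)


@dataclass
class ConversionTrace:
    """Dense (t, T, α, dα/dt) arrays for one heating ramp."""

    t: np.ndarray
    T: np.ndarray
    alpha: np.ndarray
    rate: np.ndarray
    ramp: HeatingRamp
    processes: tuple[KineticProcess, ...]
    per_process_alpha: np.ndarray | None = None  # shape (n_proc, n_t)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.alpha) < -1e-12):
            raise ValueError("conversion must be non-decreasing")
        if self.alpha.max() > 1.0 + 1e-6:
            raise ValueError("internal consistency error: alpha exceeds 1")


@dataclass
class DSCCurve:
    """Synthetic heat-flow curve, exo-up convention."""

    T: np.ndarray
    phi: np.ndarray  # W·g⁻¹
    dH_total: float  # J·g⁻¹
    baseline: np.ndarray
    q_plus: float  # °C·min⁻¹
    sign_convention: str = "exo up"


@dataclass(frozen=True)
class PeakMetrics:
    """Characteristics of a dα/dt peak.

    ``T_on5`` and ``T_end5`` are the 5 %-of-peak-height crossings used to
    bound the kinetic effect; ``t_p`` is the (refined) peak time on the ramp.
    """

    T_p: float
    t_p: float
    T_on5: float
    T_end5: float
    height: float
    width_t: float
    asymmetry: float


# ---------------------------------------------------------------------------
# model functions


def f_alpha(process: KineticProcess, alpha):
    """Evaluate the model shape function f(α) for ``process``.

    Accepts scalars or arrays with α in [0, 1); α = 1 is allowed and maps to
    0 for both models (fully converted material has zero rate).
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie within [0, 1]")
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if process.model == "ac":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(a > 0, a, 1.0) ** process.M * (1.0 - a) ** process.N
        out = np.where(a > 0, out, 0.0 if process.M > 0 else (1.0 - a) ** process.N)
    else:
        m = process.m
        interior = (a > 0) & (a < 1)
        out = np.zeros_like(a)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = -np.log1p(-a[interior])
            out[interior] = m * (1.0 - a[interior]) * g ** (1.0 - 1.0 / m)
        if m == 1.0:
            out = 1.0 - a  # first order, defined on the whole interval
        elif m < 1.0:
            # (−ln(1−α))^(1−1/m) diverges at α → 0 for m < 1; the rate
            # K·f(α) still integrates, the pointwise value at exactly 0 is
            # left at 0 and integration is seeded away from it.
            pass
    return float(out[0]) if scalar else out


def rate_constant(E: float, lnA: float, T):
    """Arrhenius rate constant K = exp(lnA − E/(R·T)), s⁻¹."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return np.exp(lnA - E / (R * T))


# ---------------------------------------------------------------------------
# forward simulation


def _grid(ramp: HeatingRamp, dT: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(round((ramp.T_end - ramp.T_start) / dT))
    T = ramp.T_start + dT * np.arange(n + 1)
    return ramp.t_of_T(T), T


def _jma_alpha_on_grid(proc: KineticProcess, t: np.ndarray, T: np.ndarray) -> np.ndarray:
    theta = np.exp(proc.lnA) * cumulative_simpson(
        np.exp(-proc.E / (R * T)), x=t, initial=0.0
    )
    with np.errstate(over="ignore"):
        return -np.expm1(-np.where(theta > 0, theta, 0.0) ** proc.m)


def _ac_alpha_on_grid(
    proc: KineticProcess, ramp: HeatingRamp, t: np.ndarray, alpha0: float
) -> np.ndarray:
    def rhs(ti, a):
        a = min(max(a[0], 0.0), 1.0)
        return [rate_constant(proc.E, proc.lnA, ramp.T_of_t(ti)) * f_alpha(proc, a)]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [alpha0 if proc.M and proc.M > 0 else 0.0],
        t_eval=t,
        method="LSODA",
        rtol=1e-12,
        atol=1e-15,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed for AC process (E={proc.E}, "
            f"T range {ramp.T_start:.1f}-{ramp.T_end:.1f} K): {sol.message}"
        )
    return np.clip(sol.y[0], 0.0, 1.0)


def simulate_conversion(
    processes: Sequence[KineticProcess] | KineticProcess,
    ramp: HeatingRamp,
    dT: float = DEFAULT_DT_K,
    ac_alpha0: float = AC_ALPHA0,
) -> ConversionTrace:
    """Simulate α(t) and dα/dt under a linear heating ramp.

    JMA sub-processes use the closed-form route α = 1 − exp(−θ^m) with θ
    computed by quadrature on a fixed grid of temperature step ``dT``; AC
    sub-processes are integrated with an adaptive stiff ODE solver seeded at
    ``ac_alpha0``.  Multi-process sets combine independently as
    α_total = Σ dh_frac·α_i.
    """
    if isinstance(processes, KineticProcess):
        processes = [processes]
    processes = tuple(processes)
    _check_dh_fracs(processes)
    if dT > 0.02:
        raise ValueError("temperature step must be <= 0.02 K")
    t, T = _grid(ramp, dT)
    per = np.empty((len(processes), t.size))
    rate = np.zeros(t.size)
    for i, p in enumerate(processes):
        if p.model == "jma":
            a = _jma_alpha_on_grid(p, t, T)
        else:
            a = _ac_alpha_on_grid(p, ramp, t, ac_alpha0)
        per[i] = a
        rate += p.dh_frac * rate_constant(p.E, p.lnA, T) * f_alpha(p, a)
    alpha = np.einsum("i,ij->j", [p.dh_frac for p in processes], per)
    alpha = np.minimum.accumulate(np.clip(alpha, 0.0, 1.0)[::-1])[::-1]
    alpha = np.maximum.accumulate(alpha)
    return ConversionTrace(
        t=t, T=T, alpha=alpha, rate=rate, ramp=ramp,
        processes=processes, per_process_alpha=per,
    )


def simulate_isothermal(
    process: KineticProcess, T: float, t: np.ndarray, ac_alpha0: float = AC_ALPHA0
) -> np.ndarray:
    """Conversion α(t) during an isothermal hold at temperature ``T`` (K).

    JMA uses the closed form α = 1 − exp(−(K t)^m); AC integrates the ODE.
    """
    t = np.asarray(t, dtype=float)
    K = rate_constant(process.E, process.lnA, T)
    if process.model == "jma":
        return -np.expm1(-((K * t) ** process.m))
    ramp = HeatingRamp(T, T + 1.0, 1.0)  # dummy, unused

    def rhs(ti, a):
        return [K * f_alpha(process, min(max(a[0], 0.0), 1.0))]

    sol = solve_ivp(rhs, (t[0], t[-1]), [ac_alpha0], t_eval=t, rtol=1e-10, atol=1e-13)
    return np.clip(sol.y[0], 0.0, 1.0)


def synthesize_dsc(
    trace: ConversionTrace, dH_total: float, baseline: np.ndarray | float = 0.0
) -> DSCCurve:
    """Build an exo-up heat-flow curve Φ = ΔH·dα/dt + baseline (W·g⁻¹)."""
    base = np.broadcast_to(np.asarray(baseline, dtype=float), trace.T.shape).copy()
    phi = dH_total * trace.rate + base
    return DSCCurve(
        T=trace.T, phi=phi, dH_total=dH_total, baseline=base, q_plus=trace.ramp.q_plus
    )


def dsc_peak_area(curve: DSCCurve, ramp: HeatingRamp | None = None) -> float:
    """Integral of (Φ − baseline) over time, J·g⁻¹."""
    q = curve.q_plus / 60.0
    t = (curve.T - curve.T[0]) / q
    return float(trapezoid(curve.phi - curve.baseline, t))


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # vertex of the parabola through three points (used to refine a discrete
    # maximum); falls back to the middle point for degenerate triples
    c = np.polyfit(x - x[1], y, 2)
    if c[0] >= 0:
        return x[1], y[1]
    xv = -c[1] / (2 * c[0])
    return x[1] + xv, np.polyval(c, xv)


def peak_metrics(trace: ConversionTrace) -> PeakMetrics:
    """Locate the dα/dt peak and its 5 %-height onset/endset.

    The peak temperature is refined parabolically through the three grid
    points bracketing the discrete maximum; the 5 % crossings are found by
    linear interpolation.  Raises if the maximum sits at a grid boundary
    (peak truncated by the ramp window).
    """
    r = trace.rate
    k = int(np.argmax(r))
    if k == 0 or k == r.size - 1:
        raise ValueError("peak truncated by ramp window")
    T_p, height = _parabolic_vertex(trace.T[k - 1 : k + 2], r[k - 1 : k + 2])
    thresh = 0.05 * height
    below_on = np.nonzero(r[:k] < thresh)[0]
    above_end = np.nonzero(r[k:] < thresh)[0]
    if below_on.size == 0 or above_end.size == 0:
        raise ValueError("peak truncated by ramp window")
    i = below_on[-1]
    T_on5 = float(np.interp(thresh, r[i : i + 2], trace.T[i : i + 2]))
    j = k + above_end[0]
    T_end5 = float(np.interp(thresh, r[j : j - 2 : -1], trace.T[j : j - 2 : -1]))
    q = trace.ramp.q_K_s
    return PeakMetrics(
        T_p=float(T_p),
        t_p=float(trace.ramp.t_of_T(T_p)),
        T_on5=T_on5,
        T_end5=T_end5,
        height=float(height),
        width_t=(T_end5 - T_on5) / q,
        asymmetry=(T_p - T_on5) / (T_end5 - T_p),
    )
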