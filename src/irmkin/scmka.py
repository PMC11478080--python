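"""Single-curve multivariate kinetic analysis (sc-MKA).

sc-MKA fits one (or several) dα/dt or heat-flow curves with a sum of
JMA/autocatalytic processes by bounded nonlinear least squares while the
activation energy of each process is held fixed at the value obtained from
the Kissinger analysis.  The objective is the weighted residual sum of
squares

    RSS = Σ_j Σ_k  w_j · (Yexp_{j,k} − Ycal_{j,k})²,
    w_j = 1 / ( |[dα/dt]_max|_j + |[dα/dt]_min|_j ),

so curves of different magnitude contribute comparably.  Free parameters are
the pre-exponential lnA, the kinetic exponents (m, or M and N) and, for
multi-process curves, the enthalpy fractions.  Optimization is multistart
bounded least squares from a fixed lattice of starting exponents; results
are deterministic.

The module also provides the E–A compensation line and the reconstruction of
the rate constant K(T) = exp(lnA(T) − E(T)/(R·T)), including the detection
of an interior maximum of K between the glass transition and melting — the
signature of a temperature-dependent activation energy.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.optimize import least_squares

from .irm_delay import DelayedTrace
from .kinetics_models import (
    HeatingRamp,
    KineticProcess,
    R,
    f_alpha,
    rate_constant,
)

__all__ = [
    "MKACurve",
    "MKAProblem",
    "MKAFit",
    "curve_weight",
    "objective",
    "fit_curve",
    "fit_delayed_trace",
    "correlation",
    "compensation_and_K",
]

logger = logging.getLogger(__name__)

#: Bounds used during optimization (pre-exponential bounds are taken
#: relative to the starting value).
BOUNDS = {"m": (0.5, 4.0), "M": (0.0, 2.0), "N": (0.2, 3.0), "lnA_halfwidth": 10.0}

#: Multistart lattice: JMA exponent starts × lnA offsets around the
#: Kissinger-implied value (8 restarts).
M_STARTS = (1.0, 1.5, 2.5, 3.5)
LNA_OFFSETS = (-1.0, 1.0)
AC_STARTS = ((0.3, 0.8), (0.3, 1.5), (0.8, 0.8), (0.8, 1.5))


@dataclass
class MKACurve:
    """One observed curve entering an sc-MKA problem.

    ``y`` is the observed quantity on the (t, T) grid: a dα/dt series
    (``target="rate"``) or a baseline-subtracted heat flow in W·g⁻¹
    (``target="phi"``, scaled by ``dH_total`` in the model).
    """

    t: np.ndarray
    T: np.ndarray
    y: np.ndarray
    ramp: HeatingRamp
    target: str = "rate"
    dH_total: float = 1.0
    #: optional dense (t, T) grid for model evaluation; when set, the model
    #: is computed on it and interpolated onto the observation times (used
    #: for coarsely sampled delayed series).
    model_t: np.ndarray | None = None
    model_T: np.ndarray | None = None

    @property
    def weight(self) -> float:
        return curve_weight(self.y)


@dataclass
class MKAProblem:
    """Model specification: per-process template with fixed E.

    The template processes supply the model kind, the fixed activation
    energy and the starting values of the free parameters (lnA, exponents,
    dh_frac).
    """

    curves: list[MKACurve]
    template: tuple[KineticProcess, ...]

    def __post_init__(self) -> None:
        self.template = tuple(self.template)
        if not self.curves:
            raise ValueError("at least one curve is required")


@dataclass
class MKAFit:
    """Optimized parameter set and diagnostics of an sc-MKA fit."""

    processes: tuple[KineticProcess, ...]
    rss: float
    r: float
    log10_one_minus_r: float
    status: str
    n_restarts: int
    n_evaluations: int


def curve_weight(y) -> float:
    """Eq-style curve weight w = 1/(|max| + |min|) of the observed series."""
    y = np.asarray(y, dtype=float)
    w_den = abs(float(y.max())) + abs(float(y.min()))
    if w_den == 0:
        raise ValueError("constant zero series has no defined weight")
    return 1.0 / w_den


def correlation(y_obs, y_cal) -> tuple[float, float]:
    """Product-moment correlation r and log10(1−r), clipped at −16."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_obs.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(y_obs) == 0:
        raise ValueError("constant observed series has no defined correlation")
    r = float(np.corrcoef(y_obs, y_cal)[0, 1])
    return r, math.log10(max(1.0 - r, 1e-16))


# ---------------------------------------------------------------------------
# forward model on a curve grid


def _ac_alpha_rk4(p: KineticProcess, t: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Fixed-step RK4 integration of the AC rate law on a dense (t, T) grid.

    Used inside the optimizer where thousands of forward evaluations are
    needed; on the fitting grids in use the step error is far below the
    residuals being minimized.  Seeded at a small positive conversion when
    M > 0 (the AC model has f(0) = 0 there).
    """
    M, N = p.M, p.N
    K = rate_constant(p.E, p.lnA, T)
    K_mid = rate_constant(p.E, p.lnA, 0.5 * (T[:-1] + T[1:]))

    def f(a):
        if a <= 0.0:
            return 0.0 if M > 0 else (1.0 - a) ** N
        if a >= 1.0:
            return 0.0
        return a**M * (1.0 - a) ** N

    alpha = np.empty(t.size)
    a = 1e-8 if M > 0 else 0.0
    alpha[0] = a
    for i in range(t.size - 1):
        h = t[i + 1] - t[i]
        k1 = K[i] * f(a)
        k2 = K_mid[i] * f(a + 0.5 * h * k1)
        k3 = K_mid[i] * f(a + 0.5 * h * k2)
        k4 = K[i + 1] * f(a + h * k3)
        a = min(a + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, 1.0)
        alpha[i + 1] = a
    return alpha


def _model_rates(
    processes: Sequence[KineticProcess], t: np.ndarray, T: np.ndarray,
    ramp: HeatingRamp,
) -> np.ndarray:
    """Total dα/dt of a process set evaluated on a (t, T) grid."""
    fracs = np.array([p.dh_frac for p in processes])
    fracs = fracs / fracs.sum()
    total = np.zeros(t.size)
    for p, frac in zip(processes, fracs):
        if p.model == "jma":
            theta = np.exp(p.lnA) * cumulative_simpson(
                np.exp(-p.E / (R * T)), x=t, initial=0.0
            )
            with np.errstate(over="ignore"):
                alpha = -np.expm1(-np.where(theta > 0, theta, 0.0) ** p.m)
        else:
            alpha = _ac_alpha_rk4(p, t, T)
        total += frac * rate_constant(p.E, p.lnA, T) * f_alpha(p, np.clip(alpha, 0, 1))
    return total


def _curve_model(curve: MKACurve, processes: Sequence[KineticProcess]) -> np.ndarray:
    if curve.model_t is not None:
        dense = _model_rates(processes, curve.model_t, curve.model_T, curve.ramp)
        y = np.interp(curve.t, curve.model_t, dense)
    else:
        y = _model_rates(processes, curve.t, curve.T, curve.ramp)
    if curve.target == "phi":
        y = curve.dH_total * y
    return y


def objective(problem: MKAProblem, processes: Sequence[KineticProcess]) -> float:
    """Weighted RSS of a trial process set over all curves of the problem."""
    rss = 0.0
    for curve in problem.curves:
        resid = curve.y - _curve_model(curve, processes)
        rss += curve.weight * float(resid @ resid)
    return rss


# ---------------------------------------------------------------------------
# parameter packing


def _pack(template: Sequence[KineticProcess]) -> tuple[np.ndarray, list, list]:
    x0, lo, hi = [], [], []
    half = BOUNDS["lnA_halfwidth"]
    for p in template:
        x0.append(p.lnA)
        lo.append(p.lnA - half)
        hi.append(p.lnA + half)
        if p.model == "jma":
            x0.append(p.m)
            lo.append(BOUNDS["m"][0])
            hi.append(BOUNDS["m"][1])
        else:
            x0 += [p.M, p.N]
            lo += [BOUNDS["M"][0], BOUNDS["N"][0]]
            hi += [BOUNDS["M"][1], BOUNDS["N"][1]]
    if len(template) > 1:
        for p in template:
            x0.append(p.dh_frac)
            lo.append(0.02)
            hi.append(1.0)
    return np.array(x0), lo, hi


def _unpack(x: np.ndarray, template: Sequence[KineticProcess]) -> tuple[KineticProcess, ...]:
    procs, i = [], 0
    for p in template:
        lnA = x[i]
        i += 1
        if p.model == "jma":
            procs.append(replace(p, lnA=lnA, m=float(np.clip(x[i], 0.5, 4.0))))
            i += 1
        else:
            procs.append(replace(p, lnA=lnA, M=float(max(x[i], 0.0)),
                                 N=float(max(x[i + 1], 1e-6))))
            i += 2
    if len(template) > 1:
        w = np.maximum(x[i : i + len(template)], 1e-6)
        w = w / w.sum()
        procs = [replace(p, dh_frac=float(wi)) for p, wi in zip(procs, w)]
    return tuple(procs)


def _starting_points(template: Sequence[KineticProcess]) -> list[np.ndarray]:
    """Fixed multistart lattice over exponents × lnA offsets."""
    x0, _, _ = _pack(template)
    starts = []
    any_jma = any(p.model == "jma" for p in template)
    exp_lattice = M_STARTS if any_jma else AC_STARTS
    for exp_start, dlnA in itertools.product(exp_lattice, LNA_OFFSETS):
        x = x0.copy()
        i = 0
        for p in template:
            x[i] += dlnA
            i += 1
            if p.model == "jma":
                x[i] = exp_start if np.isscalar(exp_start) else exp_start[0]
                i += 1
            else:
                pair = exp_start if not np.isscalar(exp_start) else (0.5, 1.0)
                x[i], x[i + 1] = pair
                i += 2
        starts.append(x)
    return starts


def fit_curve(problem: MKAProblem, multistart: bool = True) -> MKAFit:
    """Bounded least-squares sc-MKA fit with E fixed.

    Restarts from a fixed lattice of exponents and lnA offsets around the
    template (Kissinger-implied) values; the best-of-restarts by RSS wins.
    Deterministic for a fixed problem.
    """
    template = problem.template
    x0, lo, hi = _pack(template)
    sqrt_w = [math.sqrt(c.weight) for c in problem.curves]

    n_eval = 0

    def residuals(x):
        nonlocal n_eval
        n_eval += 1
        procs = _unpack(x, template)
        out = []
        for c, sw in zip(problem.curves, sqrt_w):
            try:
                model = _curve_model(c, procs)
            except Exception:
                # forward-simulation failure at trial parameters: large
                # finite penalty keeps the optimizer inside the feasible set
                model = np.full_like(c.y, 1e3 * (1.0 + abs(c.y).max()))
            out.append(sw * (c.y - model))
        return np.concatenate(out)

    starts = [np.clip(x0, lo, hi)]
    if multistart:
        starts += [np.clip(s, lo, hi) for s in _starting_points(template)]
    best = None
    n_ok = 0
    for s in starts:
        try:
            sol = least_squares(residuals, s, bounds=(lo, hi), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except Exception as exc:
            logger.debug("restart failed: %s", exc)
            continue
        if sol.success:
            n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return MKAFit((), math.inf, math.nan, math.nan, "failed", len(starts), n_eval)
    procs = _unpack(best.x, template)
    y_obs = np.concatenate([c.y for c in problem.curves])
    y_cal = np.concatenate([_curve_model(c, procs) for c in problem.curves])
    r, log1mr = correlation(y_obs, y_cal)
    return MKAFit(
        processes=procs,
        rss=objective(problem, procs),
        r=r,
        log10_one_minus_r=log1mr,
        status="converged" if n_ok else "failed",
        n_restarts=len(starts),
        n_evaluations=n_eval,
    )


def fit_delayed_trace(
    delayed: DelayedTrace,
    template: KineticProcess,
    multistart: bool = True,
) -> MKAFit:
    """Refit a delayed sampled rate series with E fixed at truth.

    The observed series is ``delayed.rate_d`` at the acquisition-end
    temperatures; the model side is the undelayed kinetic model evaluated on
    the dense source grid and interpolated to the sample points — the
    operation an experimenter performs on a set of discrete spectra.
    """
    src = delayed.source
    curve = MKACurve(
        t=delayed.t2,
        T=delayed.T2,
        y=delayed.rate_d,
        ramp=src.ramp,
        target="rate",
        model_t=src.t,
        model_T=src.T,
    )
    problem = MKAProblem([curve], (replace(template, dh_frac=1.0),))
    return fit_curve(problem, multistart=multistart)


# ---------------------------------------------------------------------------
# E–A compensation and rate-constant reconstruction


def compensation_and_K(
    T_points: Sequence[float],
    lnA_points: Sequence[float],
    E_of_T: Callable[[np.ndarray], np.ndarray],
    T_grid: np.ndarray,
) -> dict:
    """E–A compensation line and the reconstructed rate constant K(T).

    Fits lnA linearly against T over the supplied (T, lnA) triples, then
    evaluates K(T) = exp(lnA(T) − E(T)/(R·T)) on ``T_grid`` and reports an
    interior maximum of K if one exists (the behaviour expected between T_g
    and T_m when E falls with temperature faster than the Boltzmann factor
    grows).

    Returns a dict with ``lnA_coeffs`` (slope, intercept vs T), ``K``,
    ``T_grid`` and ``T_K_max`` (None when K is monotone on the grid).
    """
    T_points = np.asarray(T_points, dtype=float)
    lnA_points = np.asarray(lnA_points, dtype=float)
    if T_points.size < 3:
        raise ValueError("compensation fit needs at least 3 (T, lnA) points")
    slope, intercept = np.polyfit(T_points, lnA_points, 1)
    T_grid = np.asarray(T_grid, dtype=float)
    lnA_grid = slope * T_grid + intercept
    E_grid = np.asarray(E_of_T(T_grid), dtype=float)
    K = np.exp(lnA_grid - E_grid / (R * T_grid))
    k = int(np.argmax(K))
    T_K_max = None
    if 0 < k < K.size - 1:
        c = np.polyfit(T_grid[k - 1 : k + 2] - T_grid[k], K[k - 1 : k + 2], 2)
        if c[0] < 0:
            T_K_max = float(T_grid[k] - c[1] / (2 * c[0]))
        else:
            T_K_max = float(T_grid[k])
    return {
        "lnA_coeffs": (float(slope), float(intercept)),
        "T_grid": T_grid,
        "K": K,
        "T_K_max": T_K_max,
    }
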