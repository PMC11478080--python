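"""Kissinger analysis: constant and temperature-dependent activation energy.

The Kissinger equation relates the heating rate q⁺ and the temperature of
the rate maximum T_p of an Arrhenian single-process transformation,

    ln(q⁺ / T_p²) = −E/(R·T_p) + const,

so a linear fit of y = ln(q⁺/T_p²) against x = 1/T_p yields E = −slope·R.
When the dependence is curved, a low-order polynomial fit of y(x) gives a
temperature-dependent activation energy through the local slope,
E(T) = −R·dy/dx evaluated at x = 1/T.

A pseudo-Kissinger shift is also provided for the glass transition: given
T_g at one heating rate and the structural-relaxation activation energy Δh*,
T_g at any other rate follows from the Arrhenius shift
1/T_g(q) = 1/T_g(q₀) + (R/Δh*)·ln(q₀/q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .kinetics_models import R

__all__ = [
    "KissingerSet",
    "KissingerFit",
    "kissinger_transform",
    "fit_linear",
    "fit_poly_E_of_T",
    "pseudo_kissinger_tg",
]


@dataclass(frozen=True)
class KissingerSet:
    """Transformed (q⁺, T_char) points: x = 1/T, y = ln(q⁺/T²)."""

    q_plus: np.ndarray  # K·min⁻¹
    T_char: np.ndarray  # K
    x: np.ndarray
    y: np.ndarray
    labels: tuple = ()


@dataclass(frozen=True)
class KissingerFit:
    """Result of a linear or polynomial fit of a Kissinger set.

    For the linear kind, ``E`` (J·mol⁻¹) and its standard error are filled;
    for ``poly2`` the polynomial coefficients of y(x) (highest power first)
    define E(T) = −R·y'(1/T) through :meth:`E_of_T`.
    """

    kind: Literal["linear", "poly2"]
    coeffs: np.ndarray
    E: float | None
    E_stderr: float | None
    T_range: tuple[float, float]
    residual_variance: float

    def E_of_T(self, T) -> np.ndarray:
        """Activation energy at temperature ``T`` (K), J·mol⁻¹.

        Valid over the fitted data's temperature range; extrapolation is
        flagged with a warning.
        """
        T = np.asarray(T, dtype=float)
        if np.any(T < self.T_range[0] - 1e-9) or np.any(T > self.T_range[1] + 1e-9):
            warnings.warn(
                "E(T) evaluated outside the fitted temperature range "
                f"[{self.T_range[0]:.1f}, {self.T_range[1]:.1f}] K",
                stacklevel=2,
            )
        dy_dx = np.polyval(np.polyder(self.coeffs), 1.0 / T)
        return -R * dy_dx


def kissinger_transform(
    q_plus: Sequence[float], T_char: Sequence[float], labels: Sequence | None = None
) -> KissingerSet:
    """Build x = 1/T, y = ln(q⁺/T²) from (q⁺, T) pairs (T in kelvin)."""
    q = np.asarray(q_plus, dtype=float)
    T = np.asarray(T_char, dtype=float)
    if np.any(q <= 0) or np.any(T <= 0):
        raise ValueError("heating rates and temperatures must be positive")
    return KissingerSet(
        q_plus=q, T_char=T, x=1.0 / T, y=np.log(q / T**2),
        labels=tuple(labels) if labels is not None else (),
    )


def fit_linear(kset: KissingerSet) -> KissingerFit:
    """Ordinary least-squares line through the Kissinger set; E = −slope·R."""
    if kset.x.size < 2:
        raise ValueError("linear Kissinger fit needs at least 2 points")
    if np.ptp(kset.x) == 0:
        raise ValueError("all characteristic temperatures are equal")
    res = stats.linregress(kset.x, kset.y)
    resid = kset.y - (res.intercept + res.slope * kset.x)
    dof = max(kset.x.size - 2, 1)
    return KissingerFit(
        kind="linear",
        coeffs=np.array([res.slope, res.intercept]),
        E=-res.slope * R,
        E_stderr=res.stderr * R if res.stderr is not None else None,
        T_range=(float(kset.T_char.min()), float(kset.T_char.max())),
        residual_variance=float(resid @ resid / dof),
    )


def fit_poly_E_of_T(kset: KissingerSet, order: int = 2) -> KissingerFit:
    """Least-squares polynomial y(x); E(T) = −R·y'(1/T) over the data range."""
    n = kset.x.size
    if order >= n - 1:
        raise ValueError("polynomial order leaves no residual degrees of freedom")
    coeffs = np.polyfit(kset.x, kset.y, order)
    resid = kset.y - np.polyval(coeffs, kset.x)
    return KissingerFit(
        kind="poly2" if order == 2 else f"poly{order}",  # type: ignore[arg-type]
        coeffs=coeffs,
        E=None,
        E_stderr=None,
        T_range=(float(kset.T_char.min()), float(kset.T_char.max())),
        residual_variance=float(resid @ resid / (n - order - 1)),
    )


def pseudo_kissinger_tg(
    Tg_anchor: float,
    q_anchor: float,
    dh_star: float,
    q_target,
    form: Literal["arrhenius", "kissinger"] = "arrhenius",
):
    """Extrapolate the glass-transition temperature across heating rates.

    Parameters
    ----------
    Tg_anchor : float
        Glass-transition temperature (K) measured at ``q_anchor``.
    q_anchor, q_target : float
        Heating rates (any common unit; only their ratio enters).
    dh_star : float
        Activation energy of structural relaxation Δh*, J·mol⁻¹.
    form : {"arrhenius", "kissinger"}
        ``"arrhenius"`` (default) applies the pure Arrhenius shift
        1/T = 1/T₀ + (R/Δh*)·ln(q₀/q); ``"kissinger"`` solves the full
        Kissinger relation ln(q/T²) + Δh*/(R·T) = const instead.

    Returns the extrapolated T_g in kelvin (scalar or array).
    """
    if Tg_anchor <= 0 or q_anchor <= 0 or dh_star <= 0:
        raise ValueError("all anchor quantities must be positive")
    q_target = np.asarray(q_target, dtype=float)
    if np.any(q_target <= 0):
        raise ValueError("target heating rate must be positive")
    if form == "arrhenius":
        inv = 1.0 / Tg_anchor + (R / dh_star) * np.log(q_anchor / q_target)
        out = 1.0 / inv
    elif form == "kissinger":
        const = np.log(q_anchor / Tg_anchor**2) + dh_star / (R * Tg_anchor)

        def solve_one(q):
            f = lambda T: np.log(q / T**2) + dh_star / (R * T) - const
            return optimize.brentq(f, 50.0, 2000.0)

        out = np.vectorize(solve_one)(q_target)
    else:
        raise ValueError(f"unknown pseudo-Kissinger form {form!r}")
    return float(out) if out.ndim == 0 else out
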