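"""Two-component spectral unmixing: degree of crystallinity from Raman series.

A crystallizing amorphous drug produces Raman spectra that migrate from a
"fully amorphous" to a "fully crystalline" borderline spectrum.  Within a
chosen analysis window the baseline-corrected spectrum is decomposed by
nonnegative least squares on the two baseline-corrected references,

    s(ν) ≈ c_a · s_amorphous(ν) + c_c · s_crystalline(ν),
    α_c = c_c / (c_a + c_c),

which is scale-invariant and exact on any noise-free convex combination of
the references.  The per-acquisition α_c(T) series then yields the
characteristic temperature T_IRM at the first upward crossing of a
threshold conversion (0.63 by default, the fingerprint value of
nucleation-growth kinetics and close to the inflection of a sigmoidal α-T
curve).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "AlphaSeries",
    "baseline_subtract",
    "unmix",
    "alpha_series",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.63
DEFAULT_ANCHOR_POINTS = 5


@dataclass
class Spectrum:
    """One acquisition: counts on a strictly increasing wavenumber grid."""

    wavenumber: np.ndarray  # cm⁻¹
    counts: np.ndarray
    T_stamp: float = np.nan  # K
    t_stamp: float = np.nan  # s

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("spectrum counts must be finite")


@dataclass
class SpectrumSeries:
    """Ordered spectra plus the borderline references and analysis window."""

    spectra: list[Spectrum]
    amorphous_ref: Spectrum
    crystalline_ref: Spectrum
    window: tuple[float, float]

    def __post_init__(self) -> None:
        grid = self.amorphous_ref.wavenumber
        for s in [self.crystalline_ref, *self.spectra]:
            if s.wavenumber.shape != grid.shape or not np.allclose(s.wavenumber, grid):
                raise ValueError("all spectra of a series must share one grid")
        stamps = [s.T_stamp for s in self.spectra]
        if np.any(np.diff(stamps) < 0):
            raise ValueError("temperature stamps must be non-decreasing")


@dataclass
class AlphaSeries:
    """Unmixed degree-of-crystallinity series and its threshold crossing."""

    T: np.ndarray
    alpha_c: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    T_IRM: float | None = None
    alpha_raw: np.ndarray | None = None  # pre-clip values, for diagnostics


def _window_slice(wavenumber: np.ndarray, window: tuple[float, float]) -> slice:
    lo, hi = window
    if lo >= hi:
        raise ValueError("analysis window must satisfy w_lo < w_hi")
    i0, i1 = np.searchsorted(wavenumber, [lo, hi + 1e-12])
    if i1 - i0 < 2 * DEFAULT_ANCHOR_POINTS:
        raise ValueError("analysis window narrower than twice the anchor band")
    return slice(i0, i1)


def baseline_subtract(
    wavenumber: np.ndarray,
    counts: np.ndarray,
    window: tuple[float, float],
    n_anchor: int = DEFAULT_ANCHOR_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear baseline through the window-edge anchor bands, subtracted.

    The baseline is the straight line through the mean (wavenumber, counts)
    of the first and last ``n_anchor`` points of the window.  Returns the
    window wavenumbers and the corrected counts.
    """
    sl = _window_slice(np.asarray(wavenumber, float), window)
    w = np.asarray(wavenumber, float)[sl]
    c = np.asarray(counts, float)[sl]
    if w.size < 2 * n_anchor:
        raise ValueError("analysis window narrower than twice the anchor band")
    x0, y0 = w[:n_anchor].mean(), c[:n_anchor].mean()
    x1, y1 = w[-n_anchor:].mean(), c[-n_anchor:].mean()
    slope = (y1 - y0) / (x1 - x0)
    return w, c - (y0 + slope * (w - x0))


def unmix(
    spectrum: Spectrum,
    amorphous_ref: Spectrum,
    crystalline_ref: Spectrum,
    window: tuple[float, float],
    n_anchor: int = DEFAULT_ANCHOR_POINTS,
) -> float:
    """Two-component NNLS unmixing → degree of crystallinity α_c.

    All three spectra are baseline-corrected within the window before the
    nonnegative least-squares decomposition.  α_c = c_c/(c_a + c_c) is
    invariant to an overall intensity scaling of the spectrum.
    """
    _, s = baseline_subtract(spectrum.wavenumber, spectrum.counts, window, n_anchor)
    _, a = baseline_subtract(
        amorphous_ref.wavenumber, amorphous_ref.counts, window, n_anchor
    )
    _, c = baseline_subtract(
        crystalline_ref.wavenumber, crystalline_ref.counts, window, n_anchor
    )
    A = np.column_stack([a, c])
    cond = np.linalg.cond(A)
    if cond > 1e6:
        warnings.warn(
            f"near-collinear reference spectra (condition number {cond:.2g})",
            stacklevel=2,
        )
    coef, _ = nnls(A, s)
    total = coef.sum()
    if total == 0:
        raise ValueError("unmixing degenerate: both component weights are zero")
    return float(coef[1] / total)


def alpha_series(
    series: SpectrumSeries,
    threshold: float = DEFAULT_THRESHOLD,
    clip: bool = True,
    monotonize: bool = False,
) -> AlphaSeries:
    """Unmix every spectrum of a series and locate the T_IRM crossing.

    T_IRM is the temperature of the first upward crossing of ``threshold``
    by linear interpolation; ``None`` (with a log notice) when the series
    never crosses.  ``monotonize`` applies an isotonic (running-maximum)
    clip before the crossing search.
    """
    raw = np.array(
        [
            unmix(s, series.amorphous_ref, series.crystalline_ref, series.window)
            for s in series.spectra
        ]
    )
    T = np.array([s.T_stamp for s in series.spectra])
    a = np.clip(raw, 0.0, 1.0) if clip else raw.copy()
    if monotonize:
        a = np.maximum.accumulate(a)
    T_IRM = None
    above = a >= threshold
    if above.any() and not above[0]:
        k = int(np.argmax(above))
        T_IRM = float(
            np.interp(threshold, [a[k - 1], a[k]], [T[k - 1], T[k]])
        )
    elif above[0]:
        T_IRM = float(T[0])
    else:
        logger.info("alpha_c series never crosses the %.2f threshold", threshold)
    return AlphaSeries(T=T, alpha_c=a, threshold=threshold, T_IRM=T_IRM, alpha_raw=raw)
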