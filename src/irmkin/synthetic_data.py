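"""Synthetic inputs for the pipeline and packaged reference tables.

Two kinds of data live here:

* **Printed reference tables** for griseofulvin (GRIS) and indomethacin
  (IMC): characteristic DSC temperatures/enthalpies per heating rate, the
  published acquisition-delay simulation-study tables, and the constants
  used by the regression tests (Δh* for structural relaxation, the
  Kissinger activation energies of the two GRIS crystallization peaks).
  These are immutable fixtures with a checksum guard.

* **Generators** that emulate the raw measurements the analysis modules
  consume: multi-process exothermic DSC curves with a sigmoidal step
  baseline and additive noise, Gaussian-band borderline Raman reference
  spectra, and in situ Raman spectral time series whose mixing fraction
  follows a delayed conversion trace with multiplicative intensity
  fluctuation, additive counts noise and per-acquisition baseline drift.
  Every generator is deterministic under a fixed seed and returns the
  ground truth next to the data, so closed-loop generate → analyze →
  compare tests are the natural acceptance surface for all noisy-path code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .irm_delay import DelayedTrace, SamplingScheme, delay_transform
from .kinetics_models import (
    ConversionTrace,
    DSCCurve,
    HeatingRamp,
    KineticProcess,
    simulate_conversion,
    synthesize_dsc,
)
from .raman_unmix import Spectrum, SpectrumSeries

__all__ = [
    "NoiseModel",
    "DH_STAR_J_MOL",
    "GRIS_E1_J_MOL",
    "GRIS_E2_J_MOL",
    "gris_table1",
    "imc_table2",
    "delay_table3",
    "delay_table4",
    "gen_reference_spectra",
    "gen_irm_series",
    "gen_dsc_set",
    "gris_like_preset",
    "irm_closed_loop_kissinger",
]

#: Activation energy of GRIS structural relaxation Δh*, J·mol⁻¹.
DH_STAR_J_MOL = 379_000.0
#: Kissinger activation energy of the GRIS crystallization pre-peak, J·mol⁻¹.
GRIS_E1_J_MOL = 110_400.0
#: Kissinger activation energy of the GRIS main crystallization peak, J·mol⁻¹.
GRIS_E2_J_MOL = 71_800.0


@dataclass(frozen=True)
class NoiseModel:
    """Noise applied to synthetic Raman acquisitions.

    ``sigma_mult`` is the relative per-acquisition intensity fluctuation
    (spot defocus, grain movement), ``sigma_add`` the additive counts noise
    expressed as a fraction of the tallest reference band, and
    ``baseline_drift`` a linear per-acquisition baseline tilt in the same
    fractional units.  Identical seeds give bit-identical output.
    """

    sigma_mult: float = 0.02
    sigma_add: float = 0.005
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_mult, self.sigma_add) < 0 or self.baseline_drift < 0:
            raise ValueError("noise magnitudes must be non-negative")


# ---------------------------------------------------------------------------
# packaged tables (values as printed; temperatures °C, rates °C·min⁻¹)

_GRIS_TABLE1 = """\
q_C_min,Tg_C,Tg_pseudo,Tini_C,Tp1_C,dHc_J_g,Tp2_C,Tm_ons_C,Tm_p_C,dHm_J_g
0.13,68.3,True,52.6,58.7,48.2,59.9,203.7,209.0,84.3
0.32,70.6,True,55.3,67.0,55.7,68.7,206.0,211.4,88.4
0.65,72.5,True,62.4,74.5,54.8,79.8,208.2,213.7,107.4
1.3,74.3,True,65.7,79.1,55.8,90.0,211.0,214.8,104.4
1.95,75.4,True,70.9,82.9,53.2,97.7,212.7,215.6,111.0
2.6,76.2,True,77.4,84.8,50.8,101.1,213.0,215.9,113.8
3.25,76.8,True,81.3,87.5,48.8,106.0,214.1,216.6,115.9
4.55,77.7,True,82.8,88.9,60.8,107.1,214.3,216.8,124.1
6.5,78.6,True,85.9,93.7,57.2,113.1,215.0,217.4,116.7
9.75,79.7,False,89.4,97.6,63.5,115.0,215.7,217.9,123.0
"""

_IMC_TABLE2 = """\
q_C_min,Tg_C,Tini_C,Tp_C,dHc_J_g,Tm_p1_C,dHm1_J_g,Tm_p2_C,dHm2_J_g
0.13,28.4,63.6,65.1,55.6,,,155.3,103.5
0.32,28.7,68.0,69.9,61.5,,,156.2,104.8
0.65,31.0,72.6,74.6,56.8,148.4,16.3,157.2,95.6
1.3,32.1,76.9,79.2,61.4,149.3,32.0,157.1,87.5
1.95,33.6,79.7,82.2,59.0,148.9,39.3,156.8,72.8
2.6,34.9,79.9,82.9,62.0,150.6,35.3,157.3,80.9
3.25,35.4,79.9,83.0,60.1,152.0,65.4,158.5,57.6
4.55,36.1,84.2,87.0,56.8,152.3,76.0,158.7,41.8
6.5,37.9,89.9,93.7,58.7,152.9,73.1,159.0,29.5
9.75,38.9,95.2,100.3,65.2,153.1,68.4,159.2,27.4
"""

# second simulation round: constant peak position and point density
# (m = 3, q⁺ = 1 °C·min⁻¹), E–A pairs with their published refit results
_DELAY_TABLE3 = """\
E_kJ_mol,lnA,t_IRM_s,m_d,lnA_d,dlnA,A_ratio
50,10,300,3.05,9.864,0.136,0.873
75,19,212,3.03,18.861,0.139,0.870
100,27.7,159,3.02,27.565,0.135,0.874
125,36.4,130,3.02,36.264,0.136,0.873
150,45,110,3.02,44.863,0.137,0.872
175,53.7,93,3.01,53.565,0.135,0.874
200,62.3,83,3.01,62.163,0.137,0.872
"""

# third simulation round (E = 200 kJ·mol⁻¹, lnA = 70): constant-t_IRM and
# constant-density blocks across heating rates
_DELAY_TABLE4 = """\
q_C_min,m,t_IRM_s,m_d,lnA_d,density_pp
20,1,20,1.020,69.257,4
10,1,20,1.010,69.620,7
5,1,20,1.005,69.806,15
2,1,20,1.002,69.920,36
1,1,20,1.001,69.959,71
0.5,1,20,1.001,69.979,135
20,1,10,1.010,69.627,8
10,1,19.7,1.010,69.627,8
5,1,39,1.010,69.623,8
2,1,95.5,1.010,69.622,8
1,1,188,1.010,69.621,8
0.5,1,354,1.009,69.6379,8
20,3,4,3.012,69.850,6
10,3,4,3.006,69.924,12
5,3,4,3.003,69.961,25
2,3,4,3.001,69.984,60
1,3,4,3.001,69.992,115
0.5,3,4,3.001,69.996,222
20,3,4,3.012,69.850,6
10,3,7.8,3.012,69.851,6
5,3,15.3,3.012,69.851,6
2,3,37.5,3.012,69.851,6
1,3,68,3.045,69.832,6
0.5,3,139,3.027,69.852,6
"""

_CHECKSUMS = {
    "gris_table1": "25c64e967af2a4c3950b85bcc416d84e",
    "imc_table2": "8d8fc50597aa0654dc4131cf5c473025",
    "delay_table3": "ae90846911c2c517a94e7ef96914d728",
    "delay_table4": "2a9184890ff57885dcb59d16ce844d42",
}


def _load(text: str, name: str) -> pd.DataFrame:
    digest = hashlib.md5(text.encode()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"packaged table {name!r} failed its checksum guard")
    return pd.read_csv(StringIO(text))


def gris_table1() -> pd.DataFrame:
    """GRIS characteristic DSC temperatures/enthalpies per heating rate.

    ``Tg_pseudo`` marks rows whose T_g was extrapolated via the
    pseudo-Kissinger shift from the 9.75 °C·min⁻¹ anchor rather than
    measured.
    """
    return _load(_GRIS_TABLE1, "gris_table1")


def imc_table2() -> pd.DataFrame:
    """IMC characteristic DSC temperatures/enthalpies per heating rate."""
    return _load(_IMC_TABLE2, "imc_table2")


def delay_table3() -> pd.DataFrame:
    """Published second-round delay-study rows (constant peak and density)."""
    return _load(_DELAY_TABLE3, "delay_table3")


def delay_table4() -> pd.DataFrame:
    """Published third-round delay-study rows (t_IRM vs density blocks)."""
    return _load(_DELAY_TABLE4, "delay_table4")


# ---------------------------------------------------------------------------
# generators


def gris_like_preset(q_C_min: float) -> tuple[KineticProcess, KineticProcess]:
    """Two-process GRIS-like crystallization preset at heating rate ``q``.

    A glass–crystal surface-growth pre-peak (higher activation barrier,
    lower peak temperature) precedes the main nucleation-growth peak.  In
    the real powder the two mechanisms compete for the same amorphous
    material, so the enthalpy split shifts in favour of the pre-peak at slow
    heating (more time spent near T_g); the preset emulates that with a
    smooth rate-dependent fraction that is roughly even near 1.5 °C·min⁻¹
    and pre-peak-dominated at the slowest rates.
    """
    if q_C_min <= 0:
        raise ValueError("heating rate must be positive")
    frac_pre = 1.0 / (1.0 + (q_C_min / 1.5) ** 0.8)
    return (
        KineticProcess("jma", E=GRIS_E1_J_MOL, lnA=31.4, m=1.5, dh_frac=frac_pre),
        KineticProcess("jma", E=GRIS_E2_J_MOL, lnA=16.95, m=2.5,
                       dh_frac=1.0 - frac_pre),
    )


#: GRIS-like crystalline band set within the C–Cl stretching region
#: (centers cm⁻¹, width cm⁻¹, height a.u.).
GRIS_LIKE_BANDS = ((620.0, 4.0, 0.6), (637.0, 5.0, 1.0), (658.0, 4.5, 0.8))
GRIS_LIKE_WINDOW = (600.0, 690.0)


def _gaussians(grid: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, width, height in bands:
        out += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def gen_reference_spectra(
    grid: np.ndarray | None = None,
    bands=GRIS_LIKE_BANDS,
    amorphous_broadening: float = 2.5,
    amorphous_height: float = 0.6,
) -> tuple[Spectrum, Spectrum]:
    """Borderline amorphous/crystalline reference spectra as Gaussian bands.

    The amorphous reference reuses the crystalline band centers with widths
    broadened ``amorphous_broadening``-fold and heights scaled by
    ``amorphous_height``, which keeps the pair linearly independent while
    mimicking the band coalescence of a glass.
    """
    if grid is None:
        grid = np.arange(580.0, 710.0, 0.5)
    bands = tuple(bands)
    if any(h <= 0 or w <= 0 for _, w, h in bands):
        raise ValueError("band widths and heights must be positive")
    if amorphous_broadening <= 1.0 and amorphous_height == 1.0:
        raise ValueError("amorphous and crystalline band sets are identical")
    cryst = _gaussians(grid, bands)
    amorph = amorphous_height * _gaussians(
        grid, [(c, w * amorphous_broadening, h) for c, w, h in bands]
    )
    return (
        Spectrum(wavenumber=grid, counts=amorph),
        Spectrum(wavenumber=grid, counts=cryst),
    )


def gen_irm_series(
    processes,
    ramp: HeatingRamp,
    scheme: SamplingScheme,
    refs: tuple[Spectrum, Spectrum] | None = None,
    noise: NoiseModel = NoiseModel(),
    window: tuple[float, float] = GRIS_LIKE_WINDOW,
) -> tuple[SpectrumSeries, DelayedTrace]:
    """Synthetic in situ Raman series driven by a delayed conversion trace.

    Each acquisition mixes the two references with the delayed conversion of
    the simulated process set, s_k = (1−α_d)·amorphous + α_d·crystalline,
    then applies multiplicative intensity fluctuation, additive counts noise
    and a linear baseline drift.  Returns the series together with the
    ground-truth delayed trace for closed-loop tests.
    """
    if refs is None:
        refs = gen_reference_spectra()
    amorph, cryst = refs
    trace = simulate_conversion(processes, ramp)
    delayed = delay_transform(trace, scheme)
    rng = np.random.default_rng(noise.seed)
    scale = max(amorph.counts.max(), cryst.counts.max())
    grid = amorph.wavenumber
    rel = (grid - grid[0]) / (grid[-1] - grid[0])
    spectra = []
    for t2, T2, a_d in zip(delayed.t2, delayed.T2, delayed.alpha_d):
        s = (1.0 - a_d) * amorph.counts + a_d * cryst.counts
        s = s * (1.0 + noise.sigma_mult * rng.standard_normal())
        s = s + noise.sigma_add * scale * rng.standard_normal(grid.size)
        s = s + noise.baseline_drift * scale * (rng.uniform(-1, 1) * rel)
        spectra.append(Spectrum(wavenumber=grid, counts=s, T_stamp=T2, t_stamp=t2))
    series = SpectrumSeries(
        spectra=spectra, amorphous_ref=amorph, crystalline_ref=cryst, window=window
    )
    return series, delayed


def gen_dsc_set(
    processes,
    q_list,
    dH_total: float = 60.0,
    baseline_step: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ramp_C: tuple[float, float] = (25.0, 150.0),
) -> list[tuple[DSCCurve, ConversionTrace]]:
    """Synthetic exo-up DSC curves at several heating rates.

    The baseline is a sigmoidal step of amplitude ``baseline_step`` (W·g⁻¹)
    tied to the cumulative conversion — a simplified stand-in for the
    curved thermokinetic background under a crystallization exotherm;
    ``noise_sigma`` adds white noise (W·g⁻¹).  Ground-truth traces are
    returned alongside the curves.
    """
    rng = np.random.default_rng(seed)
    out = []
    for q in q_list:
        ramp = HeatingRamp.from_celsius(ramp_C[0], ramp_C[1], q)
        trace = simulate_conversion(processes, ramp)
        baseline = baseline_step * trace.alpha
        curve = synthesize_dsc(trace, dH_total, baseline)
        if noise_sigma > 0:
            curve.phi = curve.phi + noise_sigma * rng.standard_normal(curve.phi.size)
        out.append((curve, trace))
    return out


def irm_closed_loop_kissinger(
    process: KineticProcess,
    q_list,
    density: float = 12.0,
    noise: NoiseModel = NoiseModel(sigma_mult=0.02, sigma_add=0.005, seed=0),
    threshold: float = 0.63,
    ramp_C: tuple[float, float] = (25.0, 150.0),
):
    """Full spectral pipeline closed loop: generate → unmix → Kissinger.

    For each heating rate a noisy in situ Raman series is generated with the
    acquisition time adapted to the 5 %-height peak width so that the
    sampling density stays constant across rates (the acquisition strategy
    with the smallest kinetic distortion, since the delay shift is then a
    rate-independent temperature offset).  Each series is unmixed, the
    α_c = ``threshold`` crossing temperatures are collected, and a linear
    Kissinger fit of (q⁺, T_IRM) returns the apparent activation energy.

    Returns ``(fit, T_IRM_list)``; the per-rate noise streams are derived
    deterministically from ``noise.seed``.
    """
    from dataclasses import replace

    from .irm_delay import SamplingScheme
    from .kinetics_models import peak_metrics
    from .kissinger import fit_linear, kissinger_transform
    from .raman_unmix import alpha_series

    T_irm = []
    for i, q in enumerate(q_list):
        ramp = HeatingRamp.from_celsius(ramp_C[0], ramp_C[1], q)
        trace = simulate_conversion(process, ramp)
        t_IRM = peak_metrics(trace).width_t / density
        series, _ = gen_irm_series(
            process, ramp, SamplingScheme(t_s=float(t_IRM)),
            noise=replace(noise, seed=noise.seed + 1000 * i),
        )
        result = alpha_series(series, threshold=threshold)
        if result.T_IRM is None:
            raise RuntimeError(f"no threshold crossing at q = {q} C/min")
        T_irm.append(result.T_IRM)
    return fit_linear(kissinger_transform(q_list, T_irm)), T_irm
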