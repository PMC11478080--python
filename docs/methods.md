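# Methods

This note records the models, the numerical choices and the open design
decisions behind `irmkin`, and states what the synthetic-data tests do and
do not demonstrate about real measurements.

## Kinetic model and forward simulation

Crystallization of the amorphous phase is described by the Arrhenian
solid-state rate equation dα/dt = K(T)·f(α) with K(T) = A·exp(−E/RT)
(R = 8.314 J·mol⁻¹·K⁻¹) and two shape functions: the JMA nucleation-growth
model f(α) = m(1−α)(−ln(1−α))^(1−1/m), appropriate for isokinetic
nucleation-growth transformations and characterized by negative peak
asymmetry, and the flexible autocatalytic Šesták–Berggren model
f(α) = α^M(1−α)^N.  A measured exotherm is modelled as a sum of
*independent* sub-processes, each with its own (E, lnA, exponents) and a
fraction `dh_frac` of the total enthalpy; Φ = ΔH·Σᵢ dh_fracᵢ·dαᵢ/dt plus a
baseline, exo-up.

Independence is a deliberate simplification: real growth mechanisms compete
for the same amorphous material, so measured enthalpy splits vary with
heating rate.  The GRIS-like generator preset emulates that by making the
pre-peak fraction an explicit smooth function of q⁺; the kinetics of each
sub-process remain independent.

Parameter ranges enforced on input: E > 0, m ∈ [0.5, 4] (the 1–3.5 band
covers almost all drug crystallization processes, with margin), M ≥ 0,
N > 0, Σ dh_frac = 1 ± 1e−9.  Heating rates are accepted in °C·min⁻¹ and
converted once; all internal temperatures are kelvin.

**Numerics.** Under a linear ramp the JMA solution has the closed form
α = 1 − exp(−θ^m), θ(t) = ∫K dt, evaluated by cumulative Simpson
quadrature on a fixed grid with a 0.01 K temperature step (trapezoid
quadrature at this step leaves ~3·10⁻⁸ conversion error, above the 10⁻⁶
agreement demanded of the ODE cross-check; Simpson removes it).  The grid
also makes acquisition-window sampling an interpolation problem rather than
a grid-coincidence one.  Autocatalytic processes are integrated with LSODA
(rtol 1e−12) in the simulator, seeded at α₀ = 1e−8 because f_AC(0) = 0 for
M > 0; inside the optimizer a fixed-step RK4 on the fitting grid is used
instead, whose step error is far below the residuals being minimized.
Rates are always the analytic K(T)·f(α) on the α grid — never numerical
derivatives — so fitters see no differentiation noise.  At α → 1 the JMA
rate law is singular; adaptive ODE solvers stall a few 1e−6 below full
conversion there, which is why oracle comparisons are made for α ≤ 0.9995.

**Peak metrics.** The dα/dt maximum is refined parabolically through the
three bracketing grid points; onset/endset are the 5 %-of-peak-height
crossings by linear interpolation; `width_t` is their separation in time
and the asymmetry is (T_p − T_on5)/(T_end5 − T_p).  A maximum on the grid
boundary raises an error ("peak truncated by ramp window") rather than
returning metrics of a clipped peak.

## Kissinger analysis

ln(q⁺/T_p²) vs 1/T_p is fit by unweighted ordinary least squares
(no weighting scheme is standard for these 6–10-point sets);
E = −slope·R with the standard error propagated from the slope.  The
relation is exact for first-order kinetics and an approximation otherwise;
for m = 3 at the lowest barrier considered (50 kJ·mol⁻¹, E/RT ≈ 17) the
recovery bias is about −0.4 %, shrinking with E/RT.  For curved sets a
second-order polynomial in 1/T is fit and E(T) = −R·dy/dx at x = 1/T is
reported **only over the data's temperature range**; extrapolation warns.

The pseudo-Kissinger T_g shift uses the pure Arrhenius form
1/T_g(q) = 1/T_g(q₀) + (R/Δh*)·ln(q₀/q) by default, which reproduces the
packaged GRIS extrapolated-T_g column from the single 9.75 °C·min⁻¹ anchor
to < 0.15 °C with Δh* = 379 kJ·mol⁻¹.  The full Kissinger form (with the
T² term, effective barrier Δh* + 2RT) is available by flag; it lands
≈ 0.17 °C *above* the Arrhenius value at the slowest rate.

## sc-MKA fitting

The objective is RSS = Σⱼ Σₖ wⱼ(Yexpⱼₖ − Ycalⱼₖ)² with the per-curve
weight wⱼ = 1/(|max| + |min|) of the observed rate series (for a single
curve the weight only scales the objective and does not move the optimum).
Activation energies are fixed; free parameters are lnA, the exponents and,
for multi-process curves, the enthalpy fractions (positive weights
normalized to the simplex inside the model).  Optimization is SciPy's
bounded trust-region least squares, restarted from a fixed lattice —
m ∈ {1, 1.5, 2.5, 3.5} (or (M, N) ∈ {0.3, 0.8} × {0.8, 1.5}) crossed with
lnA offsets ±1 around the starting value — with the lowest-RSS restart
winning; everything is deterministic.  Bounds: m ∈ [0.5, 4], M ∈ [0, 2],
N ∈ [0.2, 3], lnA within ±10 of its start.  The number of processes is
user-specified, not auto-selected.  Fit quality is reported as the
product-moment correlation r between observed and calculated curves and as
log₁₀(1 − r) clipped at −16.

When E and lnA have been determined at several peak temperatures, the E–A
compensation line is a linear fit of lnA against T, and
K(T) = exp(lnA(T) − E(T)/RT) is reconstructed on a stated grid; an interior
maximum (the signature of an activation energy falling faster with T than
the Boltzmann factor rises, as happens between T_g and T_m for IMC-like
data) is located by parabolic refinement.

## The acquisition-delay model

A spectrum summed over n_s scans of t_s seconds accumulates signal for
t_IRM = t_s·n_s while the sample heats from T₁ to T₂.  Attributing the
measured crystallinity to the window end overstates the temperature; the
package models the measured value as the true conversion half-way through
the window, α_d(T₂) = α(t₂ − t_IRM/divisor) with divisor = 2 by default
(configurable in [1, 2]; values toward 1 suit signals dominated by the
window start).  Acquisition windows tile the ramp back to back from
t_offset = 0 (first acquisition starts with the ramp; the choice only
shifts the sampling phase), dropping the last partial window.  The sampling
density is counted as window-end temperatures inside the undelayed peak's
5 %-height bounds (points per peak, p/p).

The delayed rate series attached to the samples is the **exact derivative**
of the delayed conversion — the analytic source rate evaluated at
t₂ − t_IRM/2.  A finite-difference mode (centered differences of the
sampled α_d, one-sided at the ends) is provided for comparison because it
is what an experimenter can compute from discrete spectra, but it is not
the default: at 4–8 p/p the FD operator broadens the sampled peak enough to
bias the refit JMA exponent by ≈ −0.3, an artifact of the numerical
differencing an analyst would (and should) avoid by fitting α_d directly or
by smoothing, and one that would swamp the genuine delay distortion under
study, which is an order of magnitude smaller.

With the exact derivative, the delay study shows clean structure: the
refit exponent is distorted by the temperature-scale mismatch only,
m_d/m ≈ (1 + q⁺·t_IRM/(2T_p))², at most a few hundredths across m = 1–3.5
at 5–20 p/p; the pre-exponential ratio follows
ln(A/A_d) ≈ E·δT/(R·T_p²) with δT = q⁺·t_IRM/2, so A_d/A is constant
across heating rates when t_IRM is adapted to hold the density constant,
and decays toward larger distortions at fast rates when t_IRM is fixed —
which is what bends the apparent Kissinger slope (a true 200 kJ·mol⁻¹
barrier reads ≈ 168 with t_IRM = 20 s over q⁺ = 0.5–20 °C·min⁻¹).  The
delayed peak temperature used for those Kissinger fits is
T_p,d = T_p + q⁺·t_IRM/2, the maximum of the continuous delayed curve.

Simulated study ramps run 25–150 °C (a typical hot-stage program; every
studied peak fits inside).  The exponent-robustness sweep widens this to
−50 to 250 °C because first-order peaks at the lowest barrier have onset
tails longer than 60 K.  Points-per-peak counts are sensitive at the ±1–2
level to the window-tiling phase, i.e. to the ramp start; values are
reported as counted.  For the sweep the acquisition time is adapted per
exponent to hit fixed densities of 7 and 15 p/p — inside the 5–20 p/p band
a practitioner would target — because the exponent distortion grows with
t_IRM, not with density per se.

## Spectral unmixing

The "multicomponent analysis" of commercial spectroscopy software is
realized as two-component nonnegative least squares within a stated
wavenumber window: both the spectrum and the borderline references are
baseline-corrected (straight line through the mean of 5-point anchor bands
at each window edge), then α_c = c_c/(c_a + c_c) from the NNLS
coefficients.  This is exact on noise-free convex combinations, invariant
to overall intensity scaling and to any linear baseline, and each
measurement may carry its own reference pair.  Low-frequency windows
(< 200 cm⁻¹) are avoided by default because their baseline is the least
reproducible part of a Raman spectrum.  Noisy fits can leave the window
slightly, so α_c is clipped to [0, 1] with pre-clip values retained for
diagnostics.  T_IRM is the first upward crossing of α_c = 0.63 (the
1 − 1/e fingerprint of nucleation-growth kinetics, near the sigmoid's
inflection), linearly interpolated; an optional isotonic clip is off by
default.

## Synthetic data

Reference spectra are sums of Gaussian bands in a GRIS-like 600–690 cm⁻¹
window; the amorphous variant reuses the crystalline centers with 2.5×
widths and 0.6× heights, keeping the pair linearly independent (their
windowed correlation is < 0.8).  IRM series mix the references with the
delayed conversion and apply three noise terms per acquisition:
multiplicative intensity fluctuation (default σ = 2 %, emulating spot
defocus and grain movement), additive counts noise (default 0.5 % of the
tallest band) and an optional linear baseline drift.  No quantitative
noise magnitudes exist to calibrate against; the defaults produce scatter
of the magnitude seen in routine hot-stage Raman series and are
configurable.  DSC curves get a sigmoidal step baseline proportional to
cumulative α — a separable simplification of area-proportional baseline
constructions — plus white noise.  All generators are deterministic under
a seed and return their ground truth.

What the closed loops show: that unmixing recovers the delayed conversion
to < 0.02 RMSE at these noise levels, and that the full spectral pipeline
returns the generating activation energy within a few percent when the
sampling density is held constant across rates.  What they do not show:
robustness to temperature-calibration error, reference-spectrum
variability between runs, polymorph competition (three-component spectra),
cosmic-ray spikes, or baseline shapes beyond linear-within-window — all of
which degrade real IRM kinetics and are out of scope here.

## Known limitations

* Sub-processes are kinetically independent; no shared-material competition
  or consecutive-reaction coupling.
* Constant-E Kissinger fits inherit the JMA approximation bias (≲ 0.5 %
  within the supported parameter ranges, zero for first order).
* The delay model treats the acquisition as a point sample at
  t₂ − t_IRM/divisor rather than a true integral over the window; the
  divisor is the knob that absorbs the difference, and 2 is accurate when
  α is near-linear across one window.
* Melting endotherms, glass-transition step shapes, heat-transfer
  corrections and instrument calibration are not modelled; measured
  characteristic temperatures enter only as packaged tables.
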