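# irmkin

Crystallization kinetics of amorphous drugs under linear heating, with a
model of what cumulative in situ Raman acquisition does to those kinetics.

Amorphous (glassy) forms of poorly soluble drugs such as griseofulvin
(GRIS) and indomethacin (IMC) crystallize on heating; the kinetics of that
transformation decide the shelf life of the amorphous form.  Two techniques
monitor it: differential scanning calorimetry (DSC), which measures the
heat-flow exotherm, and in situ Raman microscopy (IRM), which watches the
spectrum migrate from the amorphous to the crystalline fingerprint.  This
package is for researchers who analyze either kind of data — and who want
to know how much an IRM result is distorted by the fact that each spectrum
is *accumulated* over a finite collection time rather than measured
instantaneously.

## What it computes

The rate law is the Arrhenian solid-state kinetic equation

    dα/dt = A·exp(−E/RT)·f(α) = K(T)·f(α),      Φ = ΔH·dα/dt + baseline,

with f(α) either the Johnson–Mehl–Avrami (JMA) nucleation-growth model
`f(α) = m(1−α)(−ln(1−α))^(1−1/m)` or the autocatalytic Šesták–Berggren
model `f(α) = α^M(1−α)^N`.  On top of that:

* **Forward simulation** of α(t), dα/dt and synthetic DSC curves under a
  linear ramp `T = T₀ + q⁺t` (closed-form quadrature for JMA, stiff ODE
  for the autocatalytic model), plus peak metrics with 5 %-height
  onset/endset bounds.
* **Kissinger analysis**: `ln(q⁺/T_p²) = −E/(R·T_p) + const`, as a linear
  fit (constant E), a second-order polynomial fit (temperature-dependent
  E(T) from the local slope), and a pseudo-Kissinger Arrhenius shift that
  extrapolates T_g across heating rates from the structural-relaxation
  barrier Δh*.
* **sc-MKA** (single-curve multivariate kinetic analysis): bounded
  nonlinear least squares of rate or heat-flow curves by sums of
  JMA/autocatalytic processes with E *fixed* at the Kissinger value,
  weighted per curve by `w = 1/(|max|+|min|)` of the observed rate; E–A
  compensation lines and K(T) reconstruction with interior-maximum
  detection.
* **Acquisition-delay model**: a spectrum collected over `t_IRM = t_s·n_s`
  seconds and ending at temperature T₂ reports the delayed conversion
  `α_d(T₂) = α(t₂ − t_IRM/2)`.  The delay-study runner quantifies the
  resulting distortions of the fitted exponent (m_d), pre-exponential
  (A_d/A) and apparent activation energy (E_d) as functions of q⁺, t_IRM
  and the sampling density in points per peak.
* **Spectral unmixing**: two-component nonnegative least squares of each
  baseline-corrected spectrum against fully-amorphous/fully-crystalline
  references → α_c(T) and the characteristic temperature T_IRM at the
  α = 0.63 crossing.
* **Synthetic data generators** for every input above (noisy DSC sets,
  Gaussian-band reference spectra, delayed IRM spectral series), each
  returning its ground truth for closed-loop testing.

## Worked example

Packaged characteristic-temperature tables give the activation energies of
the two GRIS crystallization peaks and the extrapolated glass-transition
temperatures:

```sh
$ irmkin kissinger --fixture gris_tp1 --dh-star-kj-mol 379 --outdir out
linear: E = 110.5 +/- 2.8 kJ/mol
pseudo-Kissinger Tg column written
```

110.5 kJ·mol⁻¹ is the barrier of the surface (glass–crystal) growth
pre-peak; the `pseudo_tg.csv` column starts at 68.3 °C for the slowest ramp
(0.13 °C·min⁻¹), the T_g shift implied by Δh* = 379 kJ·mol⁻¹.

The acquisition-delay study — simulate a peak, sample it in back-to-back
`t_IRM` windows, shift each point by `t_IRM/2`, refit with E fixed at
truth:

```sh
$ printf 'E_J_mol,lnA,m,q_C_min,t_IRM_s\n50000,10,3,1,300\n200000,62.3,3,1,83\n' > rows.csv
$ irmkin delay-study --config rows.csv --outdir out
 E_J_mol  lnA model  q_C_min  t_IRM_s  density_pp   m      m_d     lnA_d  A_ratio  converged
 50000.0 10.0   jma      1.0    300.0           7 3.0 3.052306  9.863734 0.872610       True
200000.0 62.3   jma      1.0     83.0           7 3.0 3.011582 62.163399 0.872319       True
```

Reading the first row: a slow-crystallizing peak (E = 50 kJ·mol⁻¹,
ln A = 10, m = 3, 1 °C·min⁻¹) sampled with 300-s acquisitions lands 7
points inside the peak; the refit exponent is barely distorted
(m_d = 3.05) but the apparent pre-exponential drops to A_d/A ≈ 0.873 —
the kinetic curve looks shifted 2.5 K late.  At constant sampling density
this ratio is the same for *any* (E, lnA) pair peaking at the same
temperature (compare the second row), which is why adapting `t_IRM` to the
heating rate is the recommended acquisition strategy: a constant-density
series leaves the Kissinger slope — and hence E — undistorted, whereas a
constant `t_IRM = 20 s` series biases a true 200 kJ·mol⁻¹ barrier down to
an apparent ≈ 168 kJ·mol⁻¹.

The same study is available in Python via
`irmkin.irm_delay.run_delay_study`, and the full spectral closed loop
(simulate → delay → generate noisy spectra → unmix → Kissinger on the
α = 0.63 crossings) via `irmkin.synthetic_data.irm_closed_loop_kissinger`.

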