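# Methods

This note documents the models, numerical choices and known limitations of
`soedkit`.  Units throughout: concentrations in µM, time in s, depth in cm,
fluence rate in mW/cm², total fluence in J/cm².

## Kinetic model

The macroscopic type-II model eliminates the sub-microsecond triplet and
singlet intermediates by a quasi-steady-state reduction, leaving three slow
states per depth: sensitizer [S₀], oxygen [³O₂] and the cumulative reacted
dose [¹O₂]ᵣₓ.  It is valid on time scales of seconds to hours; nothing in
the integrator steps below that.  Two variants are implemented:

* **in-solution** (`simulate_invitro`): full photobleaching denominator
  (x+1) with x = σ([S₀]+δ), optional quencher term k₇[A]τΔ in the oxygen
  equation.  With [A] = 0 the sensitizer and oxygen equations coincide, so
  Δ[³O₂](t) = Δ[S₀](t) exactly — asserted in the tests as an integrator
  diagnostic (observed drift < 10⁻⁷ µM).
* **in-tissue** (`simulate_invivo`): the small-bleaching limit x ≪ 1
  (denominator 1) plus a perfusion supply term g·(1 − [³O₂]/[³O₂]_baseline).
  The baseline defaults to the initial oxygen and can be set independently,
  which also exposes the dark-relaxation limit used as a linear-ODE oracle.

The instantaneous singlet-oxygen concentration is [¹O₂] = τΔ·d[¹O₂]ᵣₓ/dt,
so rx(t) = (1/τΔ)∫[¹O₂]dt.  That identity — verified to < 10⁻⁴ relative
against the integrator — is what makes the cumulative/instantaneous
slope-ratio analysis recover τΔ.

Numerics: `scipy.integrate.solve_ivp` (LSODA), rtol 10⁻⁸, atol 10⁻¹⁰ µM.
Depth-resolved runs stack independent copies of the system on a depth grid
(default Δd = 0.02 cm over [0, 1] cm), each with its local φ(d); there is no
lateral or depth oxygen diffusion.  Oxygen cannot overshoot zero: [³O₂] = 0
is an attracting equilibrium of the right-hand side, which additionally
floors the concentration; solver event detection is unnecessary and would
not compose with the stacked depth systems.  A fixed-step explicit Euler
oracle at dt = 1 ms agrees with the adaptive solution to < 0.1% on
phantom-scale runs, and the σ([S₀]+δ) ≪ 1, [³O₂] ≫ β limit reproduces the
closed-form Bernoulli solution of dS₀/dt = −ξφσS₀(S₀+δ) to < 10⁻⁴.

Volume averages use uniform-weight trapezoidal integration over depth with
an interpolated endpoint.

## Photophysical parameters

`PhotophysicalParams` carries the Photofrin constants with validation:
positivity, τΔ = 1/(k₆+k₇[A]) and β = k₄/k₂ enforced to 10⁻⁹ relative when
all members are present.  Derivations are per-molecule: the absorption
cross-section σ_A = ε·10⁹/N_A (cm²) and photon energy hc/λ give
ξ = Φ_Δ σ_A/hν, which reproduces the bundled ξ values to better than 1%;
the literal ε/hν shorthand does not, so it is not used.  Photon energy uses
exact Planck constants at the exact wavelength, not rounded table values.

Two bundled inconsistencies are stored as printed and flagged rather than
resolved: (1) the measured in-solution τΔ (9.4 µs at [A] = 0) differs from
the azide-titration intercept 1/k₆ (8.77 µs) by ~7%; the kinetic sets store
the measured τΔ together with τ_R = 1/k₆, and the titration rates live in a
separate record so the internal-consistency invariant stays enforceable.
(2) the in-tissue ξ at 523 nm is stored as the printed 8.99 × 10⁻³ although
rescaling the 632 nm value by the extinction ratio gives 9.41 × 10⁻³.

## Monte Carlo light transport

A pencil-beam kernel is simulated once per optics: photon packets with
isotropic scattering at µ_s = µ_s′ (similarity approximation — anisotropy is
never specified for these media), absorption weighting, Russian roulette
below weight 10⁻⁴ (survival 0.1), and an index-matched boundary (photons
crossing z = 0 escape).  Fluence is scored with a collision estimator on a
cylindrical (r, z) grid (default Δz = 0.02 cm, Δr = 0.05 cm); the estimator
is exact in expectation in the pure-absorber limit, which the tests use as a
Beer–Lambert oracle.  The on-axis profile for a uniform disk beam of any
radius is the area integral of the kernel over the disk — exact for a
homogeneous semi-infinite medium — so one photon batch yields both the
0.4 cm and 8 cm beams, and broad-beam ≥ narrow-beam holds bin by bin by
construction.  Standard errors come from 10 independent photon batches.
Default budget is 10⁶ photons (a second or two per optics on one CPU,
sub-percent on-axis error over the first 2 cm at phantom optics).

Observed physics worth noting: with isotropic scattering at µ_a = 0.58,
µ_s′ = 0.2 cm⁻¹ the broad-beam profile sits up to ~13% above e^(−µ_a d) near
the surface (backscatter buildup) when normalized to the *incident*
irradiance.  Normalized the way a phantom measurement is (to the fluence
rate just inside the front surface) and compared against an
amplitude-fitted exponential, broad beams track the exponential within
4–9% down to 1.3 cm while narrow beams fall more than 15% below it beyond
1.5 cm — the geometric contrast the tests encode.

## Broad-beam tissue profile

The in-tissue broad-beam profile is an explicit stand-in of the form
b·e^(−µ_att d) (so labelled in its output metadata).  Three calibrations of
b are available: closed-form 1-D diffusion theory (default; only inside the
diffusive regime µ_s′ > µ_a with 2Dµ_eff well below 1), a seeded Monte Carlo
calibration (log-linear fit of amplitude *and* attenuation over the
asymptotic window, on an adaptive grid), or a fixed/disabled value (b = 1).
Outside the diffusive regime the fallback is b = 1 with attenuation
min(µ_eff, µ_a+µ_s′) and a warning flag — µ_eff exceeds the transport
coefficient there and would be unphysical.  The ratio may exceed 1 near the
surface; that is real backscatter buildup, not an error.

## Luminescence model and fitting

Histograms are TCSPC-style: uniform bins (default 32 ns over 0–60 µs), a
boolean gate mask, integer counts.  The 1210 nm filter sees background
only; the net histogram is the per-bin difference with gate preserved.  The
pulse-response fit is Levenberg–Marquardt (`lmfit`) of the two-exponential
model plus a free offset, on gated bins only, weighted by the propagated
Poisson variance counts(1270)+counts(1210) with a floor of one count.  The
model shape is invariant under swapping the two time constants with an
amplitude rescale, so the fitter orders them and reports the larger as τΔ
(9.4 µs vs 0.43 µs for Photofrin in solution fixes the labelling).  Initial
guesses are deterministic: τΔ from the log-linear tail slope, τₜ by
inverting the peak-position relation t* = τΔτₜ/(τΔ−τₜ)·ln(τΔ/τₜ) by
bisection, amplitude from the total-count/τΔ identity.  Fits are refused
(typed error) when no signal rises above the background noise, when the
amplitude is not significant (< 5σ), when the slow lifetime is
unconstrained, or when a lifetime sticks at a bound.

Absolute count calibration (detector efficiency, solid angle) is not
modelled; all SOLD scales are arbitrary up to one instrument constant.  The
SOLD↔SOED comparison therefore checks *structure*: linearity of counts
versus the model's [¹O₂], and the slope-ratio identity that recovers τΔ —
not any particular counts-per-mM factor, whose empirical value depends on
an instrument calibration that is not reproducible from a model.

## Calibration regressions

All fits are ordinary least squares with covariance-based standard errors.

* **Bleaching line**: the rate per dose, (−d[S₀]/dt)/(φ[S₀]f), regressed on
  [S₀] pooled over runs; δ = intercept/slope, σ = slope/ξ.  The derivative
  is a centred 5-point local linear fit (raw differences amplify the 10 s
  sampling noise).  Three estimator details matter for noisy data and are
  deliberate: one-sided endpoint windows are excluded from the regression
  (their O(h) derivative bias on a curved decay inflates the intercept and
  hence δ); the [S₀] entering the regressor and the dose denominator is the
  window-smoothed value (dividing by the raw noisy readout correlates the
  errors of both axes); and points with oxygen below ~3 µM (the readout
  noise) are dropped, since the triplet-transfer fraction is unmeasurable
  there.  With these choices the synthetic three-phantom experiment returns
  δ = 25.6 ± 2.4 µM across seeds (generating value 25).
* **Quencher titration**: 1/τΔ on [A]; intercept k₆, slope k₇ — exact on
  noiseless input by linear algebra.
* **SOLD↔SOED line**: fitted with and without intercept, both R² reported;
  on intercept-bearing data the through-origin fit is necessarily worse,
  and the package reports both rather than choosing.

## Cross-wavelength conversion study

For each site in an optical-property table, each sensitizer concentration,
and each fluence rate, the in-tissue system is integrated once (depth
resolved, MC-calibrated broad-beam profiles, initial oxygen 40 µM) to the
longest treatment time, and the volume-averaged dose is read off at each
requested total fluence (treatment time = fluence/rate).  Per
(concentration, total fluence) the 630 nm dose is regressed on the 523 nm
dose; the slopes are then fitted linearly in concentration, a(c), and the
intercepts bilinearly as b(c,F) = (p·c+q)·F.  φ never denotes both
quantities: the code says `fluence_rate` (mW/cm²) and `total_fluence`
(J/cm²).  Applying the conversion outside the fitted (c, F) domain flags
the result as extrapolated.

At the patient-cohort mean optics, 630 nm light penetrates far deeper than
523 nm (µ_eff 5.3 vs ~20 cm⁻¹), so equal incident fluence produces 2–3×
more volume-averaged dose at 630 nm: a(c) > 1, growing with concentration
as the 523 nm dose saturates in the thin, oxygen-depleted surface layer.
The per-group regressions are strongly but not perfectly linear (R² ≈
0.84–0.91 on the default synthetic spread): a site is described by two
quantiles (absorption and scattering), so the cross-wavelength relation is
a 2-D family rather than a curve, and pooling fluence rates mixes
oxygen-saturation regimes.

## Synthetic data

Generators return (data, truth) pairs and are deterministic per seed
(`numpy.random.default_rng`).  Phantom scenarios sample oxygen every 5–30 s
and sensitizer every 10 s; readout noise defaults to additive 3 µM on
oxygen and multiplicative 3% on sensitizer — plausible stand-ins, since no
instrument noise figures are available; they are configurable and all
recovery claims are conditional on them.  Histogram pairs are Poisson per
bin around n_pulses × (pulse response integrated per bin)/τ_R plus a flat
gated background shared by both filters.  Optics tables draw one absorption
quantile and one scattering quantile per site and apply them to both
wavelength ranges (uniform within the published per-wavelength ranges):
the same chromophores and scatterers drive both wavelengths, and without
that pairing the cross-wavelength correlation structure the analysis relies
on would not exist.  Absorption and scattering remain independent — a known
simplification; real µ_a/µ_s′ covariance is not emulated, nor are raw
fluorescence spectra, detector afterpulsing, or instrument response.

What passing tests show, and don't: recovery results demonstrate the
estimators are unbiased and appropriately precise *under this noise model*;
real phantom data with correlated drifts, probe repositioning, or
non-Gaussian outliers can behave worse.

## Problem sizes

Defaults were chosen so a full test run and the reproduction script each
finish in well under a minute of ODE work plus a few seconds of Monte
Carlo per optics: 10⁶ photons for profile comparisons, 10⁵ for buildup
calibration, 100 seeded replicates for the recovery suites, 51-depth ODE
stacks for volume averaging.  All are parameters, not constants.

## Known limitations

* Type-I photochemistry is not modelled.
* No microscopic oxygen diffusion; the perfusion term is a single
  macroscopic supply rate g.
* The broad-beam tissue profile is a calibrated stand-in, not a validated
  heterogeneous-tissue light model; no index mismatch, no layered media.
* Only Photofrin constants are bundled; other sensitizers are user-supplied.
* The empirical absolute SOLD↔SOED conversion factor is instrument-specific
  and out of scope.
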