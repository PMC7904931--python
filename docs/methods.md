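# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a statistics-package methods appendix.  Nothing
here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dipole potential from excitation ratiometry

di-8-ANEPPS partitions into the outer leaflet of a vesicle; the local
dipole potential shifts its excitation spectrum, so the blank-corrected
ratio R_ex = I(420)/I(520) (emission 635 nm) is a ψ_d proxy.  Two linear
calibrations are carried:

* **Absolute**: ψ_d = (R_ex + b)/m with b = 0.3 ± 0.4 (dimensionless) and
  m = (4.3 ± 1.2)·10⁻³ per mV.  The intercept is implemented literally as
  a dimensionless offset added to the ratio before division, as the
  calibration is conventionally printed; since only differences are
  interpreted downstream, the intercept (and its large uncertainty)
  cancels.
* **Differential**: Δψ_d = k·ΔR_ex with k = 365 ± 102 mV per ratio unit,
  the slope appropriate for this wavelength configuration.  `rescale_slope`
  can refit k from user-supplied (R_ex, reference ψ_d) anchor pairs by
  ordinary least squares (two anchors give the two-point slope; a slope SE
  is attached only for ≥ 3 anchors); the default is the fixed constant,
  because the anchor reference values come from external literature and
  are not bundled here.

Wavelength lookup uses linear interpolation between neighbouring grid
points, so grids need not contain 420/520 exactly.  Replicate aggregation
reports the sample SD (n−1), matching the mean ± SD convention of
triplicate reporting, not the SEM.

**Error propagation.**  The two error sources — replicate scatter of the
two ratio means and the slope uncertainty — are combined in independent
quadrature:

    sd(Δψ) = sqrt( (k·σ_ΔR)² + (k_sd·ΔR)² ),  σ_ΔR = sqrt(sd_s² + sd_c²).

The combination rule is a package choice (the sources are standard, the
rule is not dictated); quadrature makes the slope term k_sd·|ΔR| a hard
floor on the reported uncertainty, which the tests assert.  Because σ_ΔR
propagates the *replicate SD* (not the SEM), the propagated value sits a
factor √n above the sampling scatter of the triplicate-mean shift; the
recovery test checks exactly that relation.

## Steady-state anisotropy

⟨r⟩ = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with G = I_HV/I_HH estimated per
repeat from its own HV/HH pair.  Aggregation is fixed as repeats → sample →
condition: each repeat is blank-subtracted component-wise and converted to
an anisotropy, the (typically seven) repeats are averaged into a
sample-level ⟨r⟩, and the condition mean ± SD is taken over independent
samples (triplicates).  Averaging anisotropies rather than intensities per
repeat is a deliberate choice where either convention is defensible; it
makes the per-repeat G correction exact.  Repeats whose blank-corrected
intensities are non-positive are excluded (with a log entry) rather than
clipped to zero, because clipping biases r upward.  No depolarization or
numerical-aperture corrections beyond G are applied.

## TCSPC lifetimes by iterative reconvolution

The decay law is a discrete sum of exponentials, Σαᵢ exp(−t/τᵢ) with
Σαᵢ = 1 and strictly increasing τᵢ, convolved with the measured IRF plus
a constant background.  Reported summary: the intensity-weighted mean
lifetime ⟨τ⟩ = Σαᵢτᵢ²/Σαᵢτᵢ, which lies between the amplitude-weighted
mean and max τ (asserted on every fitted model).

**Convolution operator.**  The IRF histogram is treated as a
piecewise-constant photon density over its channels and convolved with
each exponential *analytically*: within a constant IRF piece the
convolution integral has a closed form, and accumulating pieces gives an
exact O(N) linear recursion (implemented with `scipy.signal.lfilter`),
evaluated at channel centers.  This is exact for histogrammed IRFs —
unlike the common discrete sum over channel-center samples, whose error is
O(dt/τ) — and is what makes the forward model agree with a 64×-oversampled
quadrature oracle to < 1e-6 and the zero-noise generate→fit round trip
close exactly.  A fractional-channel IRF shift (linear interpolation of
the IRF) is a free fit parameter, the usual remedy for lamp/detection
timing offsets.

**Fit.**  The fit window runs from the rising edge (first channel ≥ 2% of
peak) to the last channel above max(background, 10) counts; the background
starting value is the median of the pre-rise channels.  The weighted least
squares is solved by *variable projection*: amplitudes and background are
linear in the model, so at every step of the Levenberg–Marquardt search
(over lifetimes and IRF shift only) they are solved exactly by weighted
non-negative least squares.  This removes the notorious amplitude/lifetime
trade-off from the nonlinear iteration; a naive all-parameter LM run stalls
on exactly this problem.  Weighting is done in two passes: a first pass
with Neyman weights 1/max(counts, 1), then one reweighting pass with
weights from the fitted expectation, 1/max(model, 1).  Pure observed-count
weighting systematically underestimates lifetimes (about −3% on the short
component of the 3/7 ns pair at 15k peak counts in our simulations); the
single model-based reweight reduces the bias below 1% while leaving the
reduced χ² calibration (~1 for Poisson data) intact.

Initial lifetimes are log-spaced across (10·dt, record/5), with up to three
deterministically jittered restarts; reduced χ² uses dof = window length −
(number of lifetimes + shift + amplitudes + background).  Components whose
fitted lifetimes collapse within 1% of each other demote the model to one
fewer component with a warning.  Non-convergence is flagged on the
diagnostics (which also carry the weighted residuals and a Wald–Wolfowitz
runs-test p-value), never raised.

**Order selection.**  `select_model` fits n = 1, 2, 3 and returns the
smallest n with reduced χ² < 1.3 whose refinement to n+1 improves it by
less than 5%, falling back to the best available fit with a warning.  The
thresholds are conventional parsimony settings, not fitted quantities.

## Synthetic-data generator

The generator emulates the acquisition design, not membrane physics:
compound effects enter only as shifted truth parameters.

* **Spectra**: two Gaussian bands (centers 420/520 nm, widths 35/40 nm)
  over a 2% flat baseline on the 400–625 nm, 1-nm grid.  Band amplitudes
  are solved from a 2×2 linear system so the blank-subtracted 420/520
  ratio equals the requested truth *exactly* before noise — band shape is
  nuisance, the ratio is the constrained observable.  Blank traces are a
  broad low hump capped at 0.7% of the labelled peak (the acquisition
  contract).  Reading noise is multiplicative log-normal with unit mean;
  the default CV of 0.007 was chosen so that two noisy readings propagate
  to a replicate ratio SD of √2·CV·R ≈ 0.02 at R ≈ 2, the scatter typical
  of triplicate ratio reporting.
* **Polarized quadruples**: noiseless components I_VV = s(1+2r),
  I_VH = s(1−r)/G, I_HV = G·s, I_HH = s reproduce (r, G) exactly under the
  analysis formula for any G; each of the 7 readings gets an independent
  log-normal factor.  `noise_cv_for_condition_sd` inverts a delta-method
  propagation — each reading contributes sensitivity K = (1+2r)(1−r)/3, so
  the triplicate condition SD is 2K·cv/√7 — to hit a requested condition
  SD (e.g. 0.002 at r = 0.165, 0.007 at r = 0.247).  Synthetic polarized
  blanks are generated proportional to the sample components (0.5%), which
  keeps blank subtraction exactly r-preserving in the zero-noise limit; a
  real scattering blank need not be proportional, so this idealization is
  listed under limitations.
* **Decays**: Gaussian IRF of FWHM 0.05 ns (the stated detection
  resolution; the true IRF shape is idealized), integrated over channels
  of 0.055517 ns, placed ~30 channels into the record to leave a pre-rise
  background region.  The expected curve is the *emitted* integer IRF
  histogram convolved with the exponential sum by the same exact operator
  the fitter uses, scaled to a peak of 15,000 counts (inside the
  10,000–20,000 acquisition band, enforced by default); observed counts
  are channel-wise Poisson draws.  The record must span ≥ 5·max τ.
* **Study**: 3 lipid systems × 8 compounds (control included) × 3
  replicates in both probe arms, each sample with its own blank, plus one
  decay per replicate; a manifest and a truth table keyed by sample_id are
  written alongside.  All randomness flows from the single study seed via
  `numpy` SeedSequence spawning; identical (design, seed) runs are
  byte-identical.

**Default ground truths.**  Control ratios 2.03 (POPC), 3.05 (POPC:Chol,
the 1.5-fold cholesterol increase) and 2.20 (ternary); compound cells are
seeded as Δψ_d/365 ratio shifts from the published change table for the
aglycones and the O-glucoside phlorizin.  The three C-glucosides
(nothofagin, 8-glucosylgenistein, 4-glucosylresveratrol) are generated as
*true nulls* (Δψ_d = 0): the study's conclusion is that C-glucosylation
abolishes the dipole-modifying activity, and encoding the small nominal
table entries (−22 … +5 mV) as real effects would make their statistical
non-detection impossible at the design's noise level — the generator
encodes the inference, so that the two-way ANOVA's failure to reject is a
meaningful recovery outcome.  Anisotropy truths are 0.165 / 0.247 / 0.235
(the ternary sits slightly below the binary liquid-ordered value), with
small fluidization effects for the stilbenes and C-glucosides in POPC
only; lifetimes are α = (0.5, 0.5), τ = (3, 7) ns everywhere except a
shortened (2.7, 6.3) ns pair for genistein (its polarity effect).

**What passing tests do and do not show.**  The generator draws
independent log-normal reading noise and Poisson counting noise with a
perfectly known forward model.  Real spectra carry correlated baseline
drift, scattering blanks, inner-filter effects, photobleaching and
probe-partitioning variability, none of which are modelled; parameter
recovery here validates the *analysis* pipeline (formulas, propagation,
fitting, selection), not robustness to those instrumental artifacts.

## Statistics

Within each lipid system, condition means are compared by one-way ANOVA
(omnibus F) followed by all-pairs Tukey HSD (statsmodels; Tukey–Kramer for
unbalanced groups so replicate dropout does not crash reporting), with the
two families of scientific interest — vs. control and glycoside vs. its
aglycone — flagged on each comparison.  Across the full design a two-way
fixed-effects ANOVA (compound × lipid system, with interaction, type-II
table) is used; treating the lipid system as a crossed fixed factor with
interaction is a package choice.  Significance ladder: * < 0.05,
** < 0.01, *** < 0.001, **** < 0.0001.

## Problem sizes and determinism

Simulation-based tests use 200–1000 Monte-Carlo repetitions for scalar
recoveries, 40–60 Poisson realizations for fit-bias checks and 50 seeds
for order-selection reproducibility; TCSPC records use 1024 channels.
These sizes give Monte-Carlo standard errors comfortably below the
tolerances they check.  Property-based tests (hypothesis) run
derandomized.  File formats store floats by shortest round-trip
representation and are re-read with round-trip parsing, so write→read is
the identity.

## Known limitations

* No vendor instrument formats (JCAMP-DX etc.); the text dialects are
  project-defined.
* No time-resolved anisotropy decays, no maximum-likelihood (Poisson
  deviance) decay estimator, no global multi-curve analysis, no lifetime
  distributions.
* Decay and IRF must share binning; resampling is refused rather than
  interpolated, to keep the fit contract exact.
* Absolute ψ_d values are reported only for controls; compound conditions
  are interpreted as shifts (the calibration intercept is unreliable).
* The IRF is idealized as Gaussian in the generator; the fitter itself
  accepts any measured IRF histogram.
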