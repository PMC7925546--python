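# Methods

This note documents the models, estimators, numerical choices and synthetic
data underlying `plaidgamma`, and what the validation suite does and does
not establish.

## Spectrum model and estimation

The stimulus-epoch LFP spectrum is modelled as

    P(f) = wb·F(f) + wg1·G(f|u1,σ1) + wg2·G(f|u2,σ2) + k0,
    F(f) = 1 / (|f−f0|^n0 + b0^n0),
    G(f|u,σ) = exp(−(f−u)²/2σ²).

F is a knee-type power law: flat near the low "initial peak" f0, decaying
with exponent n0 above it, with b0 (Hz) setting the knee scale
(F(f0) = 1/b0^n0 exactly).  The absolute value |f−f0| is a deliberate
choice: a plain difference raised to a non-integer exponent is undefined
below f0, and the symmetric form keeps the model finite on the whole fit
range while preserving monotone decay above f0.  G contributes at most 1,
so wg1, wg2 are narrow-band powers in the same units as the spectrum.

Multitaper estimation is delegated to `mne.time_frequency.psd_array_multitaper`
with time-bandwidth product 3 and 5 tapers on the 0.3–2.0 s epoch
(defaults; all configurable).

### Fitting

`fit_spectrum` minimizes log-power residuals with bounded least squares
(scipy `least_squares`, trf).  The log scale equalizes the four-decade
dynamic range between the low-frequency baseline and the gamma bumps; on
noiseless model data it recovers all eleven parameters to machine
precision, and the raw-power goodness of fit `1 − SS_res/SS_tot` is
reported alongside a log-power version (raw power is the default).

Numerical choices:

* fit range 10–150 Hz — excludes DC/very-low-frequency bins where the
  knee is unconstrained, while covering both gamma bands; an optional
  line-noise mask can drop e.g. 49–51 Hz;
* bounds: f0 ∈ [0, 20] Hz, n0 ∈ (0.1, 6], b0 ∈ (0.1, 100] Hz,
  σ ∈ [0.5, 20] Hz, u1/u2 confined to their disjoint bands, weights ≥ 0,
  k0 ∈ [0, max power]; wb is bounded within ±4 decades of a data-driven
  scale estimate;
* initialization: one data-driven start (log–log slope for n0, residual
  band peaks for the bumps) plus Latin-hypercube restarts (default 20;
  the weight axis is sampled logarithmically).  Failure of every start
  sets `converged=False` rather than raising.

The gamma bands default to 30–70 / 70–100 Hz and are configured per animal
in practice, since peak frequencies cluster per animal; the only hard
requirement is disjointness within (30, 100) Hz.

### Screening statistics

The z-score compares the stimulus spectrum to the blank-screen spectrum
bin by bin, dividing by the blank trial standard deviation; the blank trial
pool is whatever `SpectrumSet` the caller passes, so pooling blank epochs
across stimulus blocks (more degrees of freedom) or using blank-condition
trials only is the caller's choice.  Gamma SNR is the ratio of fitted
narrow-band weights (stimulus / blank); a zero blank weight reports +inf
with a flag rather than failing.

## Site selection

Thresholds are configuration with defaults MUA SNR > 2.5, z > 1.96,
spectrum gof > 0.8, Gamma SNR > 2, contrast-response gof > 0.6.  The
contrast-response screen is applied to **both** single-grating margins of
the matrix and passes if either fits well — a site driven only by the
orthogonal grating should not be discarded.  Sites missing a required
signal are labelled not-evaluable and excluded from that label's
denominator.

## Interaction index

The additive prediction subtracts the spontaneous level once:
`M2 = M1(c1,0) + M1(0,c2) − M1(0,0)`.  A variant without the subtraction
(which double-counts the offset) is selectable for sensitivity analysis.
The index is computed on unnormalized matrices — it is invariant to
positive rescaling, which the tests assert — and its (−2, 2) bound holds
whenever both block sums are positive.  A per-site bootstrap p (index < 0)
resamples trials within conditions.

Cross-signal pattern prediction uses an affine map (slope + intercept) over
all 49 cells; affine is the weaker assumption where a pure slope would
force the two signals' baselines to coincide.

## Normalization models

M0/M1/M2 as in the README; all three include the offset R0 (bounded at 0)
so model comparison is not confounded by offset handling.  Bounds:
c50 ∈ (0.001, 2], exponents ∈ (0.1, 8], k ∈ [0, 4], b ∈ [0, 1],
Rmax ∈ (0, 10×data max], R0 ∈ [0, data min].  Fits use one data-driven
start (b from the relative strength of the two single-grating margins)
plus 40 Latin-hypercube restarts by default — the 6-parameter landscape is
multimodal and cheap restarts are the robust remedy.  When the fitted b
sits within 0.02 of 0 or 1, one component is essentially unused and the
shared exponents are flagged weakly identified.  Matrices are fitted
unnormalized by default; `ResponseMatrix.normalized_copy()` reproduces the
max-normalized convention when wanted.

Contrasts are fractions (0–0.45) everywhere, so c50 values are on the
fractional scale.

## Statistics

The bootstrap test is the one-sided resampling recipe: B resamples with
replacement, K replicates satisfying the tested direction, p = 1 − K/B
(granularity exactly 1/B, bit-reproducible under a fixed seed).  Two-sided
p-values double the smaller one-sided p and cap at 1; the one-sided recipe
is the primitive.  Correlation bootstraps resample (x, y) pairs — i.e.
sites, when applied across a population.  Correlations, t-tests and the
Huber robust regression line are scipy/statsmodels calls behind this
module's surface.  Binned trends split by rank into near-equal groups
(first n mod k groups take the extra element; ties broken by stable sort),
reporting per-group mean ± sd plus the Spearman correlation of the raw
values.  No multiple-comparison correction is applied anywhere.

## Synthetic data

The generators define the validation conditions:

* **Spectra** — the analytic model times per-trial, per-bin chi-square(dof)/dof
  noise, dof = 2 × tapers = 10 by default: the sampling distribution of a
  multitaper power estimate.  Bins are independent, which real multitaper
  estimates are not (neighbouring bins share tapers); this makes the
  every-bin noise checks slightly conservative but does not affect the
  fitted parameters' expectations.
* **Matrices** — a model surface times (1 + cv·N(0,1)) per trial, clipped
  at zero; cv = 0.1 and 10 trials per condition by default, the simplest
  noise compatible with non-negative power/rate.  Real trial noise is
  typically over-dispersed and correlated across cells; recovery rates here
  are therefore upper bounds on what identical settings achieve on real
  recordings.
* **Populations** — per-signal M0 parameter draws from uniform ranges whose
  exponent boxes produce the qualitative dichotomy the pipeline is meant to
  detect: m1 − m2 > 0 for ~95% of MUA sites but a sizeable negative
  minority for gamma (~35% LG, ~44% HG).  An optional signed coupling
  shifts high-gamma m2 by −strength·gain·ΔSF, producing a monotone
  ΔSF → m1 − m2 trend of configurable sign and strength.  Covariates
  (per-signal SNR, ΔSF, ΔOri, border distance) are otherwise independent
  draws.  For selection tests, gamma-bearing sites get stimulus bumps six
  times the local baseline power (four times their blank weight) and
  spiking sites a stimulus epoch with four times the pre-stimulus standard
  deviation — comfortably past the thresholds, so label counts measure the
  pipeline's composition behaviour, not threshold borderline effects.

Passing tests on these data show that the estimators recover the generating
structure under the stated noise; they do not certify performance under
artifacts the generators omit (line noise, non-stationarity, correlated
trial noise, electrode drift).

## Problem sizes in the validation suite

Monte-Carlo sizes were chosen to make the checked properties statistically
decisive while keeping the suite quick on a single CPU: 100 replicates for
peak-frequency and m1 − m2 sign recovery (binomial SE ≈ 3% around the 90%
level), six 50-site repetitions for the M0 ≥ M2 ordering (the observed
gap is many times its spread), 10,000 simulated tests at B = 200 for
bootstrap calibration, a 40-site designed population for selection
composition, and a 120-site population for the end-to-end sign-fraction
check.  Spectrum fits inside Monte-Carlo loops use fewer restarts (4–12)
than the single-fit default of 20; with the data-driven start this does not
change the recovered optimum on these data, only the runtime.

## Known limitations

* The baseline form fixes one knee; spectra with two aperiodic regimes
  will push n0 toward a compromise value.
* With b near 0 or 1, c50/m1/m2 are informed by a single component's data
  (flagged, not corrected).
* The z-score assumes enough blank trials for a stable per-bin standard
  deviation; with very few trials the 1.96 threshold is anticonservative.
* Bootstrap p-values have resolution 1/B; B = 1000 cannot report p < 0.001.
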