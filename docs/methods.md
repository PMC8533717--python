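# Methods

This note documents the models, estimators and numerical choices behind
`spiraldx`, the rationale for the decisions that were genuinely open,
and what the synthetic cohorts can and cannot demonstrate.

## The drawing model

A spiral test yields a sequence of device samples
(x, y, z, pressure, azimuth, altitude, t).  The subject traces an
Archimedean spiral, whose defining property is that the radius grows
linearly with the winding angle about the centre:

    r(θ) = a + bθ.

Everything downstream exploits this structure: deviations from the
linear radius–angle relation quantify how far the drawing departs from
the ideal form, and the time axis carries the kinematic and tremor
content.

### Timestamp handling

Tablet logs do not state their time unit.  The reader auto-detects
milliseconds when the median positive increment exceeds 0.5 (no pen
samples slower than 2 Hz), divides accordingly, and shifts the origin so
each record starts at t = 0.  Rows whose timestamp does not increase
past the last retained row are dropped and counted; all downstream rates
are per second.

## Smoothing and differentiation

Velocity, acceleration and jerk are read off degree-4 smoothing splines
fitted independently to x(t) and y(t) (a quartic spline is the lowest
degree with a continuous third derivative).  The smoothing strength is
the FITPACK residual budget

    s = residual_scale · n · σ̂²,

with `residual_scale` = 1 by default and σ̂² a robust estimate of the
high-frequency noise variance:

    σ̂² = median((Δ³y)²) / (20 · 0.4549…),

the median of squared **third** differences scaled so iid Gaussian noise
of variance σ² yields σ² (third differences of iid noise have variance
20σ²; the median of a χ²₁ variable is 0.4549…).  Third differences
annihilate local quadratic trend, so the motion component contributes
only O(y″′·dt³) — negligible at tablet sampling rates — while
quantization and sensor noise pass through at full strength.  A simpler
first-difference proxy was rejected during development: successive
differences are dominated by pen motion rather than noise, which
inflates the budget by orders of magnitude and makes the spline smooth
away real signal; with third differences a noiseless analytic input is
interpolated essentially exactly (the suite checks a quartic is
reproduced to 1e-6 and a circle's curvature to 0.2%), while white noise
is smoothed at the noise floor.  Budgets below 1e-14 of the signal
variance are clamped to zero to keep FITPACK's knot search stable.

Derivatives are evaluated analytically from the spline **on the original
(possibly uneven) time grid**, not a resampled one: the inversion-rate
features depend on the recorded sampling process, and resampling would
alter their meaning.  Only the Fourier features resample (below).

Curvature uses the standard planar formula
κ = |x′y″ − y′x″| / (x′² + y′²)^{3/2}, with NaN where the speed falls
below 1e-8 (the curvature of a stationary pen is undefined); the
battery consumes magnitude statistics, so the unsigned form is used.

## Polar transform

The spiral centre is not recorded.  In `auto` mode the centre is taken
as the drawing's interior terminus: of the stroke's two endpoints, the
one closer to the centroid of all points (spiral tests are drawn
between centre and rim).  Explicit coordinates can be supplied instead.
θ is the atan2 angle unwrapped to a continuous signal (jumps above π
corrected by ±2π); monotonicity of θ is *not* assumed — tremor can
locally reverse the winding.  The radial derivatives drdt and d2rdt2
come from the same degree-4 spline machinery applied to r(t).

Near the centre the polar angle is ill-conditioned: at radius ρ a
positional noise of σ units perturbs θ by ~σ/ρ radians, which the
radius–angle regression amplifies by the slope b.  Samples within 2% of
the maximum radius are therefore excluded from the radius~theta
regression and from the radius spectral features.  Without this floor
the regression residuals under the null were dominated by a heavy tail
traceable entirely to the few near-centre samples.

## Pressure segmentation

The pressure trace of a spiral test is a trapezoid: a rising edge as
the pen settles, a long main phase, a falling edge at lift-off.  The
plateau level is estimated as the median of the middle 60% of samples
(robust to tremor riding on the plateau); with `plateau_frac` = 0.9 the
rising edge runs through the first sample at or above 0.9 × plateau,
the falling edge from the last such sample, and the main signal is the
remainder.  Degenerate overlaps resolve in favour of the main signal,
and the three intervals always partition the record exactly.  The
boundary rule is this package's own reconstruction of the three-way
decomposition; it is isolated behind `segment_pressure` so an alternative
rule can be swapped in without touching the features.

## The 79-feature battery

| block | contents | count |
|---|---|---|
| summary | {velocity, acceleration, jerk, pressure, curvature, drdt, d2rdt2} × {mean, sd, max, skewness, kurtosis, entropy, inversion rate} | 49 |
| regressions | {radius~theta, curvature~time, velocity~time, velocity~radius} × {R², per-sample SSR} | 8 |
| pressure components | {rising, main, falling} × {duration, range} | 6 |
| global | overall duration, total path length, normal velocity variability | 3 |
| Fourier | {radius residual, velocity, pressure} × {dominant frequency, peak power fraction, 4–7 Hz band power fraction} | 9 |
| pen angles | {azimuth, altitude} × {mean, sd} | 4 |

Definitional details:

* **Summary statistics**: sample (n−1) standard deviation; skewness and
  kurtosis as standardized third/fourth central moments (Fisher
  convention, normal → 0), NaN for constant signals.
* **Inversion rate**: sign changes in the first-difference sequence,
  zero differences skipped, divided by the record duration.  Sampling
  above the tremor frequency means a smooth oscillation at f Hz scores
  ≈ 2f s⁻¹ (one inversion per extremum) while fine random fluctuation
  scores near one per sample interval — this is why patients score
  *lower* than controls on pressure inversions.
* **Entropy**: plug-in histogram estimator, 16 equal-width bins spanning
  [min, max], in bits; constant signals → 0.
* **Regressions**: ordinary least squares; R² = 1 − SSR/SStot; SSR
  divided by n so drawings of different lengths are comparable.  The
  normalization affects scale only — the screening stage is rank-based,
  so feature ranking and pass lists are invariant to it.  Constant
  response → R² NaN, SSR 0; constant predictor → NaN features.
* **Normal velocity variability**: mean absolute deviation of speed
  from its mean, divided by mean speed — dimensionless and
  scale-invariant.
* **Fourier features**: the signal is linearly detrended, resampled at
  its median rate onto a uniform grid, and its magnitude-squared DFT
  spectrum summarized by the dominant non-DC frequency and the power
  fractions of the dominant bin and the 4–7 Hz tremor band.  The radius
  enters as its residual from the fitted radius–angle line — the raw
  radius is dominated by its own growth trend, which would mask the
  tremor peak.  Records under 32 samples or 1 s, and constant signals,
  yield NaN.
* **Pen angles**: raw (unsmoothed) azimuth/altitude means and sds;
  NaN when the dialect has no altitude column (the public ParkinsonHW
  files carry a single grip-angle field, mapped to azimuth).

The registry (name, group, novel flag) is the single source of feature
order; the default length is pinned at 79 by the suite.  Entropy bins,
the tremor band and all preprocessing knobs are configurable.

Degenerate drawings (fewer than 8 samples, all-zero pressure, all
points coincident) produce an all-NaN vector flagged `degenerate`
rather than an exception, so cohort extraction never dies on one bad
record.

## Screening

Each feature is compared between groups with the two-sample
Mann–Whitney U test and the probability-definition AUC
(P(patient > control), ties half), which equals U/(n_p·n_c) exactly —
the suite verifies the identity against brute-force pair enumeration.
P-values are two-sided; the exact null distribution is used when
n_p·n_c ≤ 400 with no ties, otherwise the normal approximation with tie
and continuity corrections.  The AUC cutoff applies to
max(auc, 1 − auc): informative features deviate in both directions
(pressure inversions and radius~theta R² are *lower* in patients).
The strict cutoffs (p ≤ 1e-5, effective AUC ≥ 0.9) are the multiplicity
control; no additional FDR procedure is layered on.  Subjects with NaN
in a feature are dropped for that feature only.

## Classification

Sparse random forests (default 100 trees, library-default impurity
splitting and feature sampling, at most a few features) are evaluated
over repeated stratified 50:50 train/test splits; repeat i seeds both
the split and the forest with `base_seed + i`, so reports are exactly
reproducible.  Stratification is deliberate: with a 62:15-style class
imbalance an unstratified half can lose every control.  AUC is computed
from the predicted patient probability (tree-vote fraction) — AUC on
majority-vote labels would be degenerate — while accuracy, precision,
recall and F1 (patient class positive) use the vote labels.  Per-repeat
confusion counts are stored and the suite recomputes the metrics from
them as a consistency check.  Static and dynamic tests are never mixed
in one table, so a subject cannot appear on both sides of a split.

## The synthetic cohort generator

One drawing is generated as:

* θ(t) advances from 0 to 2π·3 with smooth random speed modulation
  (Gaussian-smoothed white noise, relative sd `speed_irregularity`);
* r(t) = a + bθ + A_r·sin(2πf·t + φ) + N(0, jitter_sd), with f = 5 Hz
  inside the 4–7 Hz band and φ random;
* (x, y) = centre + r·(cos θ, sin θ), rounded to integer device units;
* pressure = trapezoid (1.5 s edges, plateau 900) +
  A_p·sin(2πf·t + ψ) + N(0, pressure_noise_sd), clipped at 0, rounded;
* pen angles drift slowly around fixed means; timestamps are uniform at
  the sampling rate, quantized to milliseconds.

Geometry: b = 120 units/rad about centre (3000, 3000) — outer radius
≈ 2260 device units, plausible for a high-resolution tablet and large
enough that integer quantization is a small relative perturbation.
Default duration 30 s at 133 Hz; the constructor asserts
sampling_rate > 2·tremor_freq, so generated tremor is always
representable.

Class presets (the study conditions for every distributional test):

| parameter | patient | control |
|---|---|---|
| radial tremor amplitude | 30 | 0 |
| pressure tremor amplitude | 60 | 0 |
| fine pressure noise sd | 0.5 | 2.0 |
| radial jitter sd | 1.5 | 1.0 |
| speed irregularity | 0.20 | 0.08 |

The patient preset encodes smooth band tremor with little fine noise;
the control preset the converse.  These are the smallest mechanisms that
reproduce both headline effects by construction: patients get *higher*
radius~theta residuals and a *lower* pressure inversion rate.  Tremor is
a single sinusoid with random phase — the minimal model for the
inversion-rate and regression mechanisms — not the broadband spectrum of
real parkinsonian tremor.

Per-subject random streams derive from (cohort seed, subject index), so
cohorts are reproducible and order-independent.  Written cohorts use an
8-column dialect including altitude (the simulator generates both pen
angles), so the full battery is finite on synthetic data and the disk
round-trip reproduces features exactly; real ParkinsonHW files use the
7-column dialect and altitude features are NaN there.

### Problem sizes in the suite and acceptance script

Distributional tests run on scaled-down drawings — 8 s at 80 Hz for
two-class comparisons, 6 s at 60 Hz for the many-cohort null runs —
chosen so the suite completes quickly while both rates still oversample
the tremor band severalfold.  The null-calibration check pools
feature-level Mann–Whitney rejections over 25 independent
identical-parameter cohorts of 10+10 subjects (≈ 1900 pooled tests;
constant features are excluded, since a rank test can never reject on a
constant).  The chance-level classification check averages the
repeated-evaluation mean AUC over independent 30+30 null cohorts
(three in the test suite, six in the acceptance script): at this
sample size the spurious empirical separation of any *single* null
cohort fluctuates with sd ≈ 0.05–0.1 (the forest faithfully reports
whatever accidental class gap a finite cohort happens to contain), so
the cohort-averaged value is the meaningful estimator of chance-level
behaviour.  The headline power check uses one 30+30 cohort at the full
default scale.

## What passing tests do and do not show

The synthetic cohorts demonstrate that the pipeline's machinery is
correct and calibrated: exact geometric primitives, rank statistics
matching enumeration, nominal type-I error under the null, and by-design
reproduction of the two tremor mechanisms.  They do **not** demonstrate
clinical performance: real tremor is broadband and intermittent, real
cohorts include micrographia, pen lifts, medication state and template
variation that the generator does not model, and the shipped effect
sizes produce near-perfect separation by construction.  Performance
numbers on synthetic cohorts are statements about the pipeline, not
about Parkinson's disease.

## Known limitations

* The exact feature formulas of the historical battery this registry
  mirrors are reconstructed (normal velocity variability, entropy
  estimator, Fourier set, pressure-edge boundary rule); the
  reconstructions are isolated so they can be swapped without touching
  the pipeline, and rank-based screening makes the pass lists robust to
  monotone differences in the definitions.
* Whether interior pen-lift (zero-pressure) samples should be dropped is
  exposed as a dialect choice but defaults to retention; the tests do
  not simulate pen lifts.
* No azimuth/altitude smoothing, no z-axis kinematics, no per-revolution
  sub-features, no image-based (scanned) drawings.
* The CMT (circular motion) test parses but has no dedicated feature
  semantics; analysis targets SST and DST.
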