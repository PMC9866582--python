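# Methods

This note records the models, numerical choices and known limitations of
pulsekit, in the order the pipeline runs.

## Pulse-cycle model

One cycle is the superposition of main, tidal and dicrotic waves.  All
rising and falling segments use the canonical cubic smoothstep — for a
descent from peak (tp, Yp) to zero at tz,

    Yp · (3(tz−tp)(tz−t)² − 2(tz−t)³) / (tz−tp)³,

which is continuous, attains Yp at tp, vanishes at tz and has zero slope
at both ends.  This is the only reading of the piecewise-cubic
construction consistent with a continuous waveform whose main-wave value
at the peak time equals Ym: the naive sign convention for the descending
pieces evaluates to 5·Yp at the peak, i.e. an instantaneous 4·Yp jump.
The continuity property test guards exactly this: for a cycle sampled at
fs, adjacent-sample jumps must stay below 5·Ym/(ts·fs) — an O(1/fs)
bound slightly above the steepest analytic slope (the ascending branch's
1.5·Ym/ts), while a peak discontinuity would jump by ~4·Ym regardless
of fs.

Parameters, with the generator's class-conditional defaults (uniform —
assumption-minimal given only published per-class feature ranges):

| parameter | meaning | normal | slippery |
|---|---|---|---|
| T (s) | cycle period | U(0.85, 1.1) | same |
| ts/tf | ascending/descending ratio (fixes ts) | U(0.17, 0.20) | U(0.24, 0.29) |
| b − ts | peak-to-valley delay | U(0.11, 0.14)·T | same |
| ts1 − b, T1 − ts1 | tidal peak/valley delays | U(0.09, 0.12)·T, U(0.11, 0.14)·T | same |
| ts2 − T1 | dicrotic peak delay | U(0.09, 0.12)·T | placeholder (T1+T)/2 |
| Ym (counts) | main-wave peak | U(80, 120) | same |
| Ym1/Ym, Ym2/Ym | tidal/dicrotic fractions | U(0.07, 0.12) each | Ym2 = 0 |
| c | curvature constant | U(0.28, 0.42) | same |

The timing fractions beyond ts/tf are the package's own physiological
choices (dicrotic notch near mid-cycle, dicrotic peak near 0.6·T); the
published per-wave duration ratios could not be adopted directly because
a main-wave "occupied duration" shorter than the ascending branch would
violate the model's ts < b ordering.  Records draw base parameters once
and add ±3% period / ±4% amplitude beat-to-beat jitter — small enough
that the anomaly detector's 30%/25% defaults never fire on legitimate
beats.

With Ym2 = 0 the timing placeholders (ts2, and T1 = cycle end when no
tidal valley exists) keep every downstream formula defined.  Note a
side effect the pipeline treats as a real phenomenon: when Ym2 is at
the low end of the normal range, the dicrotic bump may fail to produce
a local maximum against the descending main wave ("inconspicuous
dicrotic"), so a small fraction of normal records legitimately carry a
zero dicrotic-height feature.

## Sensor model and fixtures

The pressure-to-voltage calibration is the cubic
u = 2.333m³ − 0.689m² + 0.171m + 0.068 (m in grams); its derivative has
negative discriminant, so it is monotone over the calibrated 0–2 g
range.  It is treated as a formal calibration curve: evaluated at 2 g it
exceeds the 3.3 V electrical full scale, and the package does not force
consistency.  Contact pressure is P = mg/S with S = 0.3025π×10⁻⁴ m²;
the headline sensitivity figure divides full-scale millivolts by the
full-scale pressure rounded to 206 Pa (the 3-decimal kPa figure), which
is how the quoted 16.019 mV/Pa arises; the unrounded pressure gives
16.001 mV/Pa.  The ADC mapping y = u·4096/3.3 is real-valued by default;
integer quantization is opt-in.  The stated 0.5–100 Hz sensor band is
emulated as a 4th-order zero-phase Butterworth high-pass at 0.5 Hz (at
fs = 125 Hz only the low edge is representable); the filter's component
level realization is not modelled.

The cuff-pressure sweep fixture deflates 160 → 60 mmHg at 4 mmHg/s and
gives per-cycle amplitudes a unimodal Gaussian envelope in pressure
(σ = 18 mmHg) about a requested optimum — the oscillometric shape the
optimal-pressure selector needs.  Since no operational definition of
"optimal pressure" is standard here, the selector is argmax of
per-cycle amplitude, ties broken toward higher pressure, boundary
optima warned.

## Key-point localization

The quadratic surface fit is ordinary least squares on the design
[x², xy, y², x, y, 1]; rank deficiency (e.g. collinear scan points) is
reported by name.  The three-sensor placement is parameterized by the
center (x1, y1) and array angle θ ∈ (−π/2, π/2); the two outer points
sit ±1.5 cm along (sinθ, cosθ), which makes the 2.25 cm² adjacent
squared-spacing and collinearity constraints hold by construction and
keeps y0 < y1 < y2.  Optimization is a coarse vectorized grid
(0.05 cm / 0.02 rad) over the scanned rectangle expanded by one
spacing, followed by Nelder–Mead refinement with infeasibility
penalties; feasibility requires all three fitted amplitudes ≥ 60
counts, and an empty feasible set raises "no pulse found".  Equal-mean
ties break toward smaller |θ|, then smaller y1, making output
deterministic.  On random concave quadratics the search matches a dense
(0.01 cm / 0.01 rad) brute-force oracle to well under 0.5% of the mean
amplitude.  Amplitude constraints are checked against the fitted
surface, not raw grid values, since the optimum is generally off-grid.

## Denoising

The 5-level DWT defaults to Daubechies-4 with periodization boundary:
orthogonal, perfect reconstruction to ≤1e−8, exact Parseval.  The
shrinkage threshold is the robust universal form
N = 1.43·median(|CD1|)·√(2 ln n_eff), n_eff = 500 by default
(1.43 ≈ 0.96/0.6745 relates the absolute-value median to the noise σ);
the finest band CD1 is noise-dominated at 125 Hz, and its single N is
applied to all five detail bands.  Survivors shrink by λ = α·N with
α = 0.5 by default — the halfway compromise between hard (α = 0) and
soft (α = 1) thresholding, both of which the implementation reproduces
exactly at the endpoints.  Coefficient magnitudes never increase, so
shrinkage is non-expansive in energy.

Cycle segmentation places boundaries at onset troughs: local minima
below the 20th amplitude percentile separated by at least 0.4·fs
samples (pulse < 150 bpm); record edges count as boundaries when they
sit at trough level.  Each complete cycle is then sheared so its
endpoints match (subtracting n·tanθ with θ the start-to-end chord angle
in sample units — only tanθ matters, so the unit choice is immaterial)
and shifted so its minimum is exactly zero.  Mean filtering and spline
baseline fits are deliberately not used: the shear-plus-offset step
removes within-cycle drift without smearing edges.

On the default noise model (0.2 Hz sinusoidal drift of 3 counts, white
noise σ = 0.5 counts against ~100-count peaks) the chain reduces RMSE
against clean ground truth by well over 50%, and on noise-free input it
is a near-identity (≤2% of Ym).

## Landmarks, prediction and reconstruction

Landmarks are alternating extrema found with a prominence floor of 1%
of the main peak.  Missing structures degrade gracefully: no local
minimum after the tidal peak (slippery cycles decay monotonically)
anchors the tidal valley to the cycle end; no dicrotic maximum sets
h5 = h6 = the end value with t5 bisecting [t4, t6].

The landmark-to-parameter mapping re-anchors all times by subtracting
(t6 − T), sets Ym = h1, and only then computes Ym1 = h3 − y1(ts1) and
Ym2 = h5 − y1(ts2) with the already-determined main wave (order
matters); negative secondary amplitudes clamp to zero.  The mapping
does not determine the curvature constant c, so by default c is
estimated from the main-valley height as h2/f1(b) (the envelope equals
c there, up to the valley's small offset from b); an explicit c
suppresses the estimate.  Round-tripping synthesize → landmarks → map →
synthesize reproduces cycles to ≤5% of Ym across the generator's
parameter space.

Anomalous cycles are flagged on >30% amplitude or >25% period jumps
relative to the last valid cycle; the initial reference is the first
cycle within tolerance of the record medians, so a corrupted opening
beat cannot poison the chain.  Replacements are predicted from the last
valid cycle's landmarks (time-scaled to the flagged cycle's length) and
refined by Nelder–Mead least squares over (b, ts, c) — bounded to ±20%
for b and ts and (0, 1] for c, with the objective guaranteed
non-increasing (the original parameters are kept on any failure to
improve).  A derivative-free local fit is used because the adjustment
is a small 3-parameter polish around a good initialization; replacement
accuracy is then limited mostly by beat-to-beat variability
(mean ≈ 5%, occasionally ~10% of Ym per replaced cycle).  Unflagged
samples pass through bit-identical; a flagged first cycle with no prior
valid cycle, or an all-flagged record, is left unchanged with a warning.

The corruption model defaults to amplitude mutations; period mutations
are available but change the sample count, so no aligned clean
ground-truth trace exists for them.

## Features

Per-cycle spatio-temporal features use a valley-to-valley partition:
main duration = main-valley time, tidal = tidal-valley − main-valley,
dicrotic = remainder (zero when the dicrotic wave is absent — the
end-anchored tidal valley makes this automatic).  Ratios are stored
normalized to the main wave (t2/t1, t3/t1, h2/h1, h3/h1) plus ts/tf, so
the vector is fixed-length; records aggregate per-cycle values by
median.  These per-wave duration/height symbols are a different
namespace from the landmark times/heights and are never mixed.

Modal energies are Euclidean-norm ratios of single-band wavelet
reconstructions; with the orthogonal transform their squares sum to 1
(exactly at lengths divisible by 2⁵, to within a fraction of a percent
otherwise because trimming the padded reconstruction breaks exact
orthogonality).  The correlation filter r > 0.2 is computed per record;
because classifiers need fixed dimensionality, the layout (y6, y5, y4)
is fixed and a component failing the filter is flagged rather than
dropped.  Fy is computed per record (not per cycle): the energies are
norm ratios over the whole trace, and per-cycle energies would be
dominated by cycle-length variation.  On denoised pulse records the
scaling band Y6 (0–2 Hz, the fundamental plus the nonzero mean of
baselined cycles) dominates and Y4–Y6 pass the filter while Y1–Y3 fail.

## Classification benchmark

The default benchmark simulates 1260 records (8 cycles each, default
noise, 29% slippery — mirroring a ~100:40 subject mix; 50/50 is a
supported alternative), runs each through the denoising chain and
featurizes.  Splits are stratified 60/20/20 (756/252/252 at n = 1260).
Features are standardized with training-split statistics only.
Hyperparameters come from small fixed grids — SVM: C ∈ {0.1, 1, 10},
rbf γ ∈ {scale, 0.1, 1}; NN (single hidden layer): width ∈ {4, 8, 16},
activation identity for the "linear" cell and tanh as the RBF analog —
selected on the validation split by accuracy with a margin/probability
criterion (log-loss, or hinge loss for SVMs) breaking accuracy ties;
ties on accuracy alone are common near the accuracy ceiling and would
otherwise be broken arbitrarily by grid order.  The comparison re-splits
per seed (default 3 repeats) and averages.

What passing tests show — and what they do not: the synthetic classes
are separable nearly by construction (disjoint ts/tf generating ranges
and an exactly absent dicrotic wave), so all eight cells score near 1.0
and the comparison verifies structure (mixed features never hurt;
SVM-rbf on mixed features attains the best cell; accuracy ≥ 0.95) rather
than reproducing accuracy magnitudes reported on human data, which
reflect physiological variability the generator does not model.

## Known limitations

* The generator models one subject archetype per record with uniform
  parameter draws and small jitter; no inter-subject covariance,
  arrhythmia, sensor drift or motion artifacts beyond sinusoidal
  baseline wander.
* Landmark extraction assumes a denoised, baselined cycle; heavy
  residual noise degrades it before it degrades the classifier.
* The anomaly detector keys on amplitude/period only; a
  morphology-preserving artifact with matched amplitude passes.
* At fs = 125 Hz the upper sensor band edge (100 Hz) cannot be
  represented; only the high-pass edge is emulated.
* Timing parameters beyond ts/tf are plausible defaults, not fitted to
  published per-wave duration tables (see above).
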