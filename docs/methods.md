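# Methods

This note documents the models, numerical choices and limitations of
`emcscreen`. It covers the stimulus generator, the synthetic observer, the
preprocessing pipeline, the spatiotemporal features, the normative scoring
and the decision-tree evaluation, in that order.

## Stimulus model

Each trial is a two-dimensional Gaussian random walk sampled at the display
rate: per axis, independent `N(0, step_sd²)` increments, reflected at the
display bounds. Defaults: 6 trials × 20 s at 60 Hz (1200 samples/trial),
`step_sd = 0.25°` per sample (≈ 1.9°/s RMS drift), bounds ±15° (a 17″
monitor at 60 cm). In *displaced* mode the target additionally relocates to
a position drawn uniformly over the bounded display every 2 s (samples 120,
240, …); between jumps the walk law is unchanged. The step SD, bounds, jump
law and boundary rule are not dictated by the paradigm itself; they are
configuration, echoed into every output file. Reflection was chosen over
clipping because it keeps the step distribution unbiased away from the
walls; with the default geometry reflections are rare within a trial, and
the generator's step law is exactly Gaussian in their absence.

## Observer model

There is no public gaze dataset for this paradigm, so cohorts are simulated
from observers with known parameters; everything downstream is validated by
recovering them. The response model is

```
gaze(t) = gain · smooth(stimulus)(t − lag) + N(0, noise_sd²)
```

with these elements:

- `lag` (s): pursuit latency, applied as a whole-sample shift.
- `motor_smoothing` (s): SD of a Gaussian kernel convolved with the target
  path, modelling the low-pass character of pursuit. This is what gives the
  velocity correlogram its width — the velocity of a Gaussian walk is white
  noise, so an unsmoothed, fixed-delay response would produce a single-lag
  delta correlogram rather than the Gaussian-shaped one real trackers show.
  The kernel is applied zero-phase so `lag` remains the sole source of
  delay and latency recovery stays exact. Default 0.04 s.
- `reacquisition_delay` / `reacquisition_jitter` (s): after each
  displaced-mode jump the observer holds its pre-jump position estimate for
  `max(0, delay + N(0, jitter²))` seconds — with `search_noise_sd` extra
  positional noise — before resuming tracking. The per-jump jitter models
  trial-to-trial saccadic latency variability and spreads the
  displaced-mode correlogram.
- Blinks: a Poisson process (`blink_rate`/s). Each event ramps the vertical
  position upward at 300°/s for 3 samples (video eye trackers misread the
  closing eyelid as the pupil shooting upward) and then marks samples
  missing for the rest of `blink_duration` (default 0.2 s).

Three default phenotypes encode the qualitative group patterns of the
clinical populations: *control* (lag 0.18 s, noise 0.5°, fast
reacquisition), *glaucoma-like* (near-normal smooth pursuit, but slow —
0.45 s — and imprecise — 3° search noise — reacquisition after jumps, as
expected with peripheral field loss), *neuro-like* (elevated latency 0.33 s,
noise 2°, motor smoothing 0.08 s in both modes). Cohorts apply 10%
relative multiplicative jitter per participant. These values are modelling
choices, not clinical claims; what passing tests show is that the pipeline
separates observers whose tracking differs in these ways, not that real
patients are classified at the same accuracy.

## Preprocessing

1. Screen coordinates are converted to visual-field degrees:
   `atan(offset_mm / viewing_distance_mm)` per axis, origin at the screen
   centre, rightward/upward positive.
2. Velocities are first differences × rate, assigned to the later sample
   and front-padded so position and velocity share indexing.
3. Blink detection on the vertical velocity: spikes above 190°/s that are
   followed by a flat line (|Δv| < 1e-6°/s across at least two samples —
   the derivative-equals-zero test needs a numeric tolerance) or by missing
   data are flagged; the spike plus its flat/missing tail is dilated by 5
   samples each side and overlapping segments are merged. Isolated fast
   upward saccades with normal dynamics afterwards are deliberately not
   flagged. The threshold applies to the signed upward component, matching
   the upward-spike artifact.
4. Gap filling: each segment is filled with the average of a forward and a
   backward extrapolation from affine AR(2) models fitted by least squares
   on 10-sample context windows (one-sided at trial edges). The affine fit
   reproduces linear trends and pure sinusoids exactly; fits whose
   characteristic roots fall outside the unit circle — common on short
   noisy windows, and capable of growing by hundreds of degrees across a
   20-sample gap — are refitted about the local level with the roots shrunk
   onto the unit circle, bounding extrapolation growth to linear. Order 2
   is the smallest order that reproduces ramps and is stable to estimate
   from 10 samples.
5. A trial is discarded when blink plus missing samples exceed 33% of its
   duration (strictly; exactly 33.0% is kept).

Samples inside filled segments are included in the feature computations
(fill-then-analyse); an exclusion option exists for sensitivity analysis.

## Spatiotemporal features

Per axis and mode (40 values total; canonical order is property-major, then
horizontal before vertical, then smooth before displaced):

- **Positional error distribution.** Signed per-sample errors pooled over
  valid trials, binned at 0.5° over ±30° (bins centred on zero), unit
  mass, Gaussian-fitted. Reported mean is |μ|; amplitude is clipped to
  [0, 1]. Bin width and range are configurable and recorded in metadata.
- **Velocity correlogram.** Per-trial Pearson correlation per lag over the
  overlap (mean-removed, unit-variance, so the [−1, 1] range is guaranteed),
  lags −1…+1 s in one-sample steps, averaged pointwise across trials and
  Gaussian-fitted. Positive lag means gaze follows stimulus. Times are kept
  in seconds everywhere. Jump instants are included in displaced-mode
  correlograms. Amplitude is clipped to [−1, 1] (a least-squares Gaussian
  can overshoot a narrow peak).
- **Gaussian fits** are initialised at the curve peak with a
  half-width-at-half-maximum σ and solved by `scipy.optimize.curve_fit`
  (tolerances 1e-10), with μ constrained to the fitted x-range. Adjusted
  R² uses the p = 3 correction. Flat inputs raise a fit failure; failed
  features become NaN with a recorded reason and are median-imputed at
  training time.
- **Cosine similarity** is computed per axis on the pooled position series;
  negative values (anti-correlated tracking) are clipped to 0 with a
  warning, preserving the feature's stated [0, 1] range.
- **Observation-noise variance.** Scalar local-level model with
  `Q = var(diff(stimulus))` estimated from the pooled stimulus increments;
  `R` maximises the innovations log-likelihood of the pooled gaze series
  via bounded golden-section search over `log R ∈ [log 1e-10, log 1e4]`
  (xatol 1e-4). The level is initialised from the first observation. The
  gain recursion is data-independent and converges geometrically, so after
  400 exact steps the remaining innovations are produced with the
  steady-state gain through a linear filter; the result matches a full
  time-varying filter to ~1e-12 and statsmodels' local-level MLE to a few
  percent (cross-checked in the tests). Trials are pooled by concatenation;
  the inter-trial discontinuity enters stimulus and gaze symmetrically.

## Normative scoring

A control cohort is summarised per feature by median and MAD
(`median |Y_i − median(Y)|`); new vectors are scored with
`M = (x − median) / (1.486·MAD)` — the constant is implemented exactly as
the published formulation — and features with `|M| > 2` are flagged.
Zero-MAD features yield an explicit undefined score rather than ±∞, so
degenerate cohorts stay visible. Cohort-level stability (two control
cohorts drawn from the same observer law) is assessed on the test cohort's
per-feature median profile, which is what a cohort-comparison spider plot
shows; individual profiles against a small simulated reference flag more
often, as expected from estimation noise on both sides.

## Classification

Trees are grown by recursive binary splitting: at each node every feature
and every midpoint of consecutive distinct sorted values is evaluated, and
the split minimising the count-weighted child Gini impurity wins; ties are
broken by lower feature index, then lower threshold, making growth
deterministic across platforms. Splitting stops at purity, `max_depth`,
`min_leaf`, or an optional global split budget. Hyper-parameters are tuned
by stratified seeded 10-fold CV over a default grid (depth 1–6, min-leaf
1–5 — the grid itself is a choice), taking the lowest mean validation
error with ties to the earlier entry, then refitting on all data.
Generalisation is measured leave-one-out. NaN features are imputed with
training-set medians inside every fold. The screening task labels
participants `control` vs `patient` (= both disease phenotypes).

The published screening rule (displaced-mode vertical cosine similarity
≤ 0.74 → patient; else smooth-mode PED adjusted R² > 0.99 → healthy; else
indeterminate) is exposed as a fixed partial model; the remaining branches
of the published tree are not documented, and the axis of its second split
is not stated (horizontal by default, configurable).

Reported metrics are computed from one-vs-rest confusion-matrix
reductions; undefined ratios (zero denominators) are reported as NaN, and a
round-half-away-from-zero formatter is provided for printing.

## Problem sizes and determinism

All simulations are driven by explicit seeds through
`numpy.random.Generator`; identical seeds give byte-identical outputs. The
validation suite uses a 60-participant cohort at the full session size
(6 × 20 s × 60 Hz per mode), 7200-sample series for noise-parameter
recovery, and 200 trials for blink-detection sensitivity. The acceptance
script re-runs the same computations in ~15 s on one CPU.

## Limitations

- The observer is linear with additive Gaussian noise: no saccade main
  sequence, no predictive pursuit, no gain asymmetries, no pupil dynamics.
  Simulated displaced-mode behaviour collapses "search" into a
  hold-then-jump with extra noise.
- The normative cohort is simulated; no claim is made about real normative
  variability, age effects, or ethnicity effects.
- Classification accuracies on simulated cohorts measure pipeline
  separability under the phenotype definitions above, not clinical
  performance.
- The published tree is reproduced only to the two documented splits;
  training data for the full trees is not available.
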