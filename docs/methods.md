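# Methods

This note documents the models, numerical choices, and known limitations of
`wheelwiggle`. It is written for users who need to know exactly what the
code computes, and what passing its test suite does and does not certify.

## Task model

The package targets the head-fixed 2AFC wheel task: a Gabor patch
(0.10 cycles/visual degree) appears at ±35° azimuth at one of five
contrasts {0, 6.25, 12.5, 25, 100}%, and the mouse turns a wheel
(counterclockwise for rightward stimuli, by our sign convention positive
wheel degrees) to bring it to the center. A wheel displacement of 8.75 mm —
35 visual degrees at a gain of 4 visual deg/mm, equivalently 17.2 wheel
degrees (0.3 rad) — ends the trial. Stimulus side probabilities follow
biased blocks: 90 unbiased trials, then strictly alternating 80:20 / 20:80
blocks of 20–100 trials each. A trial begins after a self-initiated
quiescence of 0.40–0.70 s (0.2 s base plus an exponential component of
scale 0.35 s restricted to [0.20, 0.50] s). A note on that component: no
exponential truncated to [0.20, 0.50] s can have mean 0.35 s (the
truncated mean is ≈0.329 s, approaching 0.35 only in the uniform limit);
we implement rejection sampling of the 0.35 s-scale exponential and treat
the support as the binding constraint.

## Wiggle detection

Wheel position is linearly interpolated onto a uniform 1000 Hz grid,
low-pass filtered with a zero-phase (forward–backward) 3rd-order
Butterworth at 20 Hz, and differentiated by central differences. `k` is the
number of sign transitions of this velocity within [stimulus onset,
feedback]. Numerical choices:

* **Stillness dead band.** The filtered velocity is never exactly zero, and
  zero-phase filtering rings at ~1–2% of peak speed around sharp movement
  onsets. Samples with |v| ≤ max(2 deg/s, 3% of the in-window peak speed)
  are treated as zero-valued; zero-valued runs carry the preceding sign
  (an initial run takes the first non-still sign), so plateaus and filter
  ringing are not counted as direction changes. Genuine reversals pass
  through the dead band quickly and are counted once.
* **Motion onset** t₀ is the first time after stimulus onset at which the
  filtered speed stays above the stillness threshold for ≥ 20 ms (falling
  back to stimulus onset if the wheel never clearly moves).
* **Change anchoring.** Each change time is the first sample of the new
  sign; change positions are read from the filtered position. Metrics are
  anchored at (t₀, θ₀); on false starts the movement can be under way when
  the analysis window opens, so changes at or before t₀ are dropped from
  the inter-extremum segments (never from `k` itself) to keep all segment
  durations positive.
* Filtering uses `scipy.signal.filtfilt` with its default odd-reflection
  edge padding; sampling below twice the cutoff is rejected.
* The wiggle-duration definition used is the formal one — time between the
  first and last extremum — with no additional "stillness exclusion"; and
  wiggle amplitude is the *mean* inter-extremum displacement (median and
  peak-to-peak would be alternatives; the mean is what the rest of the
  pipeline assumes).

## Psychometric model and fitting

Choices follow P(right|c) = γ + (1−γ−λ)·½[1 + erf((c−μ)/(√2σ))] with
lapse rates γ, λ ∈ [0, 0.5], bias μ ∈ [−100, 100] (contrast %), and
threshold σ ∈ (0.1, 200]. Fitting maximizes the exact binomial likelihood
(trials aggregated by signed contrast) with bounded L-BFGS-B from a fixed
grid of six starting points; the best likelihood wins, making refits
deterministic. Parameter recovery at 10,000 trials is accurate to roughly
±0.01 on lapses and ±1–2 on μ, σ *provided the design contains enough
asymptotic-contrast trials*: lapse rates are identified only by saturating
contrasts, so recovery experiments weight ±100% at 20% of trials each.

## Accuracy-vs-wiggle statistics

* Octiles are equal-count quantile bins with stable tie-breaking; sessions
  with fewer than 3 trials in any bin are flagged excluded.
* The accuracy–speed relationship is a trial-level logistic regression of
  correctness on octile index (0–7); complete separation is flagged, not
  silently fit.
* Session/mouse typing regresses per-bin proportion correct on the
  k-category index {0, 1, 2, 3, ≥4}, weighted by per-bin trial counts, on
  6.25%-contrast trials. Mice are positive/negative when R² ≥ 0.1 (strong
  when R² ≥ 0.7); sessions are benefiting (r > 0.3), non-benefiting
  (r < −0.3), or neutral, where r is the weighted Pearson correlation.
* Inclusion bounds are inclusive: rt = 0.08 s is both a false start and
  the lower edge of the analysis window (false-start labeling is applied
  before windowing).
* d′ clips hit/false-alarm rates to [1/2n, 1−1/2n] before Gaussian
  inversion. Bonferroni correction defaults to α/3 ≈ 0.0167.

## Pupil analyses

Pupil diameter is normalized to the session maximum (idempotent; scale
invariant). Trial windows are half-open: baseline [−0.5, 0) s, post
[0, 0.5) s, with the onset sample belonging to post; windows without
samples yield NaN and such trials are dropped listwise from pupil analyses
only. Pupil-stratified accuracy uses half-open bins [0.10, 0.15) …
[0.40, 0.45); within each bin the speed-octile regression is fit at the
trial level (regression on octile index — using per-octile median speed is
a straightforward variant). Mixed-effects models (accuracy ~ speed + pupil
with a mouse random intercept; pupil ~ speed with a session random
intercept per session type) are estimated by REML via statsmodels; a
single-group fit degrades to OLS with an explicit flag.

## Decoding and firing-rate modulation

Spikes are counted in half-open 20 ms bins aligned to stimulus onset and
flattened per trial neuron-major to a K × (N·T) matrix. The decoder is an
L2-regularized logistic regression (C = 1, a fixed choice recorded here
because no principled value is dictated) evaluated over stratified
train/test splits (test fraction 0.2, also a fixed choice) with
seed-deterministic repeats; sessions need ≥ 20 wiggle trials and both
classes. Window comparisons decode [0, 0.2] s and [0, 1.0] s with identical
seeds. Modulation analysis converts counts to rates, smooths with a
Gaussian kernel (σ = 3 bins) along time, normalizes by (mean baseline rate
in [−0.5, 0) s + 1 spike/s), pairs each wiggle trial with the nearest
non-wiggle trial in session time (with replacement; ties to the earlier
trial), and calls a neuron modulated when a one-sided paired Wilcoxon gives
p ≤ 0.05 *and* the paired Cohen's d (mean/SD of the differences) is ≥ 0.8.
Electrode insertions pass QC with ≤ 80 μm drift and ≥ 10 units.

## Synthetic sessions: what they emulate, and what they do not

The generator reproduces the task's statistical skeleton with exact ground
truth: block structure, quiescence support, bimodal reaction times (false
starts uniform on [−0.20, 0.08] s at 5% by default; stimulus-triggered
responses 0.08 s + lognormal with overall median ≈ 0.16 s), choices from
the psychometric model with the block prior entering as an additive bias
shift (μ_eff = μ + 8%·2(p_left−½) by default; at 0% contrast in biased
blocks, correct means matching the block-majority side), and per-contrast
wiggle statistics in which wiggle probability, amplitude, and duration all
decrease with contrast.

Wheel trajectories are piecewise half-cosine segments through alternating
extrema, so the smooth velocity changes sign exactly `k_true` times;
feasibility requires the extremum excursion to exceed |D|/(k+1) for net
displacement D, and a bounded-peak-speed check rejects durations too short
for the requested k. Measurement noise is 40 Hz-low-passed white noise at
1% of the excursion by default, gated by the normalized local speed — a
rotary encoder reports a stationary wheel exactly, so noise belongs to
movement, and the gating guarantees the 20 Hz-filtered sign-change count
equals `k_true`. Spike tensors are Poisson with a seeded half of neurons
multiplying their rate by (1 + coding_strength) on their preferred side,
active throughout the window unless confined for controls — this is what
makes longer decoding windows strictly more informative. Pupil traces are
sub-0.1 Hz filtered noise with one broad excursion that sets the session
maximum (placing typical normalized values inside the analyzed 0.10–0.45
band), plus an optional transient proportional to trial wiggle speed.

Deliberately *not* emulated: learning across sessions, quiescence resets by
premature movements (reaction times below −0.20 s never occur), the
closed-loop renderer and reward hardware, retinotopy, eye movements, and
any realistic spike-train temporal structure beyond inhomogeneous Poisson.
Passing tests on these sessions certifies the *analysis code* — detection,
statistics, decoding — under known ground truth; it does not certify
effect sizes on real mice, which depend on data we do not simulate.

Study-scale conditions used by the heavier tests (chosen once as realistic
session scales): session typing uses ±0.04 accuracy per k-bin over 800
trials (the per-mouse positive-slope median reported for this behavior is
about +0.03); decoder checks use 50 neurons, 400 trials, and 25 repeats
per window across 50 sessions, with calibration at 100 repeats; modulation
recovery plants a doubled post-stimulus rate in 20 of 100 neurons with
base rates gamma-distributed around 25 Hz and 80 trial pairs.

## Known limitations

* The direction-change count is dead-band dependent by construction; data
  filtered at other cutoffs or sampled far below 1000 Hz will need the
  stillness threshold revisited.
* The weighted Pearson r of a 2-point regression is ±1 by construction;
  session typing is only meaningful with ≥ 3 populated k-bins.
* MixedLM on small group counts can hit boundary (zero-variance) REML
  solutions; results carry statsmodels' estimates without further
  correction.
* The block-prior shift on choice is a phenomenological additive bias; no
  claim is made that mice combine priors additively.
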