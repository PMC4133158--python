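# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and known limitations behind `foragedyn`.  It is the
place to look when a default looks arbitrary or a fit behaves unexpectedly.

## Data model

A recording is a strictly increasing sequence of event times (seconds from
session start) with one opaque integer option label per event, plus a
light/dark schedule (24 h period, 12 h light from a configurable onset
hour; the session-start clock hour anchors timestamps to clock time).
Cycle membership uses the half-open convention `[onset, onset + 12 h)`, so
an event exactly at light onset is light and the labels partition the
events.  An inter-choice interval (ICI) inherits the cycle label of its
*starting* event; the choice is ours (either convention changes a handful
of boundary intervals out of thousands) and is applied consistently.
Sessions are treated as one continuous stream, never split per day: all
downstream statistics are interval- or hour-of-day-based, so absolute
calendar anchoring is irrelevant.

## Descriptive temporal statistics

* Burstiness `B = (σ−m)/(σ+m)` uses the **population** standard deviation;
  with the sample SD, B of a constant train would not reach −1 exactly.
* The memory coefficient M divides the mean lagged cross-moment by the
  population SDs of the two margins (first n−1 and last n−1 intervals).
  This equals the Pearson correlation of consecutive pairs; the test suite
  checks that equivalence against `np.corrcoef` as an independent oracle.
  Zero variance in either margin is an error, never silently 0.
* Choice entropy uses non-overlapping windows (default 100 trials),
  base-2 logs, `0·log 0 ≡ 0`; a trailing partial window is dropped rather
  than reported at different variance.
* The autocorrelogram bins events (default 1 h), mean-subtracts the
  counts, and normalizes the autocorrelation to 1 at lag 0.  Period =
  mean spacing of local maxima that (a) exceed `2/√n_bins` — roughly twice
  the noise floor of an uncorrelated count series, so a homogeneous
  Poisson record yields *no* qualifying peaks rather than a spurious
  period — and (b) are separated by ≥ 12 h.  Peaks are only searched in
  the first half of the record because the biased autocorrelation estimate
  decays linearly with lag and late peaks drop below threshold, which
  would otherwise inflate the mean spacing.

## Heavy-tail fitting

The ICI distribution is modelled piecewise: a power law `f(τ) ∝ τ^(−µ)`
on `[τ_min, τ₀)` and a Weibull tail above τ₀.

* τ₀ is the interior local minimum of the ICI density on log-spaced bins
  (25/decade) smoothed with a 3-bin moving average, searched between 50
  and 1000 s.  If no interior minimum exists at that bandwidth the moving
  average widens twice (5 then 7 bins) — small samples need more
  smoothing — before the distribution is declared unimodal (an error, not
  a NaN).  A genuinely unimodal density stays monotone at every bandwidth.
  By default τ₀ is detected once on the overall distribution and reused
  for the light/dark fits, matching the observation that the crossover is
  shared across cycles; pass `tau_0` explicitly to override.
* The power-law exponent is the closed-form MLE
  `µ̂ = 1 + n/Σ ln(x_i/τ_min)` when untruncated, and a bounded 1-D
  likelihood maximization under the `[τ_min, τ₀]` normalization when
  truncated.  τ_min is selected by scanning candidates (unique values,
  quantile-subsampled to ≤ 100) for the minimum KS distance between fitted
  and empirical tail CDFs; ties break toward the smaller τ_min, keeping
  more data.
* Goodness of fit is a parametric bootstrap: simulate matched-size samples
  from the fitted model, refit each, and report the fraction of bootstrap
  KS statistics at least as large as the observed one (default 1000
  replicates; the p-value is reported, never thresholded).
* The tail Weibull MLE is `scipy.stats.weibull_min.fit` with location 0.
  Because the tail sample is left-truncated at τ₀ by construction, the
  bimodal fit first maximizes the *conditional* (truncated) likelihood,
  which removes the upward shape bias that a plain MLE shows on truncated
  samples.  When the truncated optimum places more than half of its
  fitted mass below τ₀ — i.e. the parameters are mostly determined by an
  unobservable region — the fit falls back to the plain MLE, whose scale
  parameter remains interpretable as the gap timescale.  This guard
  triggers on data whose gaps are not actually Weibull (e.g. the
  dual-state model's circadian gap mixture) and leaves well-specified
  fits untouched.
* The composite survival is a mixture continuous at τ₀:
  `S(t) = w·S_head(t) + (1−w)` below τ₀ and `(1−w)·S_wb(t)/S_wb(τ₀)`
  above, with w the observed fraction of modelled intervals below τ₀.

## Dual-state timing model

Parameters (defaults in parentheses): τ_min (10 s) and τ₀ (500 s) bound
the intra-burst power law with exponent µ (2.0); ξ (0.05) is the
per-choice probability of leaving the active state, making bout sizes
geometric with mean 1/ξ; ρ₀ (2.4×10⁻⁴ s⁻¹) is the mean inactivity rate;
P_A is the 24-vector of activity-onset probabilities per clock hour
(default: uniform over the 12 dark hours, zero in light); b_light/b_dark
(1.0/1.0) are shape exponents applied to P_A per the current hour's cycle.
These magnitudes mirror what two-week rat logs yield.

Choices we had to make where the model is underdetermined:

* The modulated inactivity rate is normalized so its 24 h time-average is
  ρ₀ (`ρ(t) = ρ₀·P_A(h)^b(h)/Z`, `Z = mean_h P_A^b`), preserving ρ₀'s
  meaning as the mean rate.
* A gap is τ₀ plus the NHPP first-arrival time (sampled by thinning
  against the peak hourly rate), so simulated gaps are always ≥ τ₀ and
  τ₀-threshold segmentation of a simulation is self-consistent.  The
  arrival itself is the first event of the next bout.  A consequence: the
  estimator ρ̂₀ = 1/mean(gap) is biased low by roughly τ₀/mean-gap (≈ 10 %
  at the defaults), plus a circadian ripple; the consistency test
  therefore runs in a uniform-profile regime where the bias is small.
* Estimators: ξ̂ = bouts/events (geometric MLE), ρ̂₀ = reciprocal mean gap,
  P̂_A = histogram of bout-start clock hours.

Least-area estimation scores a candidate (τ_min, τ₀, µ, b_light, b_dark)
by segmenting the data at the candidate τ₀, estimating (ξ̂, ρ̂₀, P̂_A),
simulating 10 replicate logs of equal duration, pooling their intervals,
and integrating the absolute difference of log₁₀ survival over a common
log₁₀-time grid (trapezoid, 200 points, survival floored at half the
resolution of the smaller sample).  All candidates consume an identical
random stream (common random numbers), so area differences reflect
parameters rather than Monte-Carlo noise; a coarse grid is refined once
around the argmin.  **Limitation:** the area statistic is nearly flat for
candidate τ₀ *below* the generative value — a smaller threshold re-labels
burst intervals as short gaps and the refitted NHPP mimics the survival
there — so τ₀ is weakly identified downward (recovery to within ±20 % is
about the resolution limit at 14-day, ~4000-event scale), while µ is
recovered sharply.

## Dual-control choice model

Value dynamics per trial t: the chosen option's goal value moves toward
its reward value, `Q_c += α_c (R_c − Q_c)`; every unchosen option decays,
`Q_u += α_u (0 − Q_u)`; habit values follow the leaky integrator
`H(t+1) = e^(−1/κ)(H(t) + c(t))`, equivalent to the kernel sum
`H_i(t) = Σ_τ e^(−τ/κ) c_i(t−τ)` (the equivalence is oracle-tested to
1e−12).  H is the raw leaky sum, not normalized; β_H absorbs the scale, so
an H saturating at `e^(−1/κ)/(1−e^(−1/κ)) ≈ κ` pairs naturally with small
β_H.  Reward values come from the generalized matching law,
`R_i ∝ rate_i^(1/a)` (max-normalized to 1), computed once from the
whole-session mean choice rates and held fixed; a is fitted jointly, which
leaves a partial a↔β_G trade-off that the max-R normalization only
mitigates.  Q and H start at 0 (first-trial likelihood is uniform).
Softmax uses max-subtraction; probabilities sum to 1 to 1e−12 at any
parameter magnitude.

Variants and free-parameter counts entering the BIC: Dual k=6
(α_c, α_u, a, κ, β_G, β_H), Goal_c+u k=4, Goal_c k=3, Habit k=2
(κ, β_H), Goal_c+Habit k=5.  An inactive system has its β forced to 0 and
its updates skipped.  Fitting is bounded L-BFGS-B (NLL tolerance 1e−8)
from multistart draws — log-uniform for the scale-type parameters
(a, κ, β_G, β_H), uniform for the learning rates — because uniform draws
essentially never initialize small gains (e.g. β_H ≈ 0.03 inside a (0, 50)
box) and multistart then misses the global optimum.  The forward NLL pass
is numba-compiled; the test suite keeps an independent pure-Python
trajectory oracle (agreement to 1e−10).

**Limitation — goal/habit degeneracy.**  The likelihood is nearly
invariant under a role swap: a slow goal system (α ≈ 1/κ) mimics the leaky
habit integrator and a fast habit (small κ) mimics fast TD, differing only
through the R-weighting of goal updates.  At N = 5000 the swapped optimum
lies within a few NLL units of the true one and is the *global* optimum on
a minority of realizations, so point recovery of (β_G, β_H, κ) is
unreliable beyond ≈ 20–35 % relative error even at the most identifiable
settings we found (fast goal α_c = 0.5, slow habit κ = 60, wide reward
spread a = 0.8).  Model *selection* is robust to this: the Dual variant
still wins BIC against its nested variants on Dual-generated data.

## Synthetic data

`generate_dataset` composes the two generative models: timestamps from the
dual-state simulator, options from the dual-control simulator mapped 1:1
onto events (no timing–choice coupling, mirroring the models' independence
over the same event stream).  Defaults emulate the study conditions:
14 days, 4 options, target choice rates (0.50, 0.25, 0.15, 0.10) feeding
the matching-law reward values, dual-state magnitudes as above, and
dual-control parameters α_c = 0.5, α_u = 0.3, a = 0.8, κ = 60, β_G = 1.0,
β_H = 0.03.  The choice parameters were frozen once after an
identifiability sweep: they reproduce the qualitative phenomena (≈ 55 %
of choices to the favorite, persistence above any frequency-matched
shuffle, heavy-tailed runs with decreasing hazard) while keeping the two
controllers at separated timescales.  What the generator does *not*
emulate: satiety/nutrition dynamics, within-bout choice–timing coupling,
day-to-day preference drift, and inter-individual variability — so green
tests certify the pipeline's statistics and estimators, not those aspects
of real behavior.

Analytic fixtures (`generate_fixture`) pin limiting values: periodic
trains (B = −1 exactly), homogeneous-Poisson intervals (B ≈ 0),
two-valued alternation (M = −1), truncated power-law samples (inverse-CDF)
and a power-law + truncated-Weibull interval mixture.

## Monte-Carlo shuffle tests

The run-structure test statistic is the sup-norm distance between the
empirical run-length survival and the mean survival of 999+
frequency-preserving shuffles; each shuffle's statistic against the
leave-one-out ensemble mean forms the null, and
`p = (1 + #{null ≥ obs})/(n_shuffles + 1)` guarantees p > 0.  The area
statistic used for timing fits is available as an alternative, but the
sup-norm is the default because it is distribution-free over run lengths.
Calibration (type-I error at nominal α on exchangeable sequences) is
verified in the test suite over 100 replicates.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make every
stochastic tolerance comfortable: 10⁵ intervals for the B/M limits, 10⁴
samples for tail-parameter recovery, 14-day simulations (~4×10³ events)
for circadian and least-area checks, N = 5000 trials × 10 seeds for
choice-model recovery and selection, and 999 shuffles × 100 replicates
for calibration.
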