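# Methods

This note records the models, conventions and numerical choices behind
`pirodyn`, in the order the pipeline applies them.

## Composite series construction

Single-turn trials are too short for attractor reconstruction, so the
cohort is pooled into one series per coordinate:

1. **Resampling** to 300 samples per trial by piecewise-linear
   interpolation onto evenly spaced abscissae spanning the original index
   range. Linear interpolation is deterministic and endpoint-exact; no
   anti-aliasing filter is applied (the trials are smooth and oversampled
   relative to the movement).
2. **Normalization** divides each coordinate by its maximum *absolute*
   value, so every column attains max |value| = 1. Coordinates can be
   negative; normalizing by the signed maximum would not bound the series
   in [−1, 1]. An all-zero column is a degenerate input and raises.
3. **Shuffle and flip**: the trials enter in a seeded uniform random order,
   and trials at even 1-based positions of that order are time-reversed.
   Reversal makes consecutive blocks meet at matching endpoints, closing
   the concatenation into a loop-like signal instead of introducing jump
   discontinuities at every block boundary.
4. **Quantile reduction**: samples strictly below the empirical
   `p_low = 0.1` quantile (type-7 / linear-interpolation convention) are
   removed, survivors keep their temporal order, and ties at the threshold
   are retained (so an all-equal series is untouched and `p_low = 0` is the
   identity). This is a trimming filter, not a quantile *transform*: a
   literal quantile function would sort the series and destroy its
   dynamics, while this pipeline proceeds to embed the output. On 4500
   samples the reduction deterministically leaves ≈ 4050 (n − ⌈0.1·n⌉ ± 1
   from threshold interpolation).

## Hurst exponent (R/S)

For log-spaced window sizes n from `min_window = 8` to N/2 (12 scales), the
series is cut into non-overlapping windows; each window contributes
R/S = (range of the cumulative mean-deviation profile) / (sample std,
ddof = 1); windows with zero variance are skipped. H is the OLS slope of
log mean(R/S) on log n.

The raw slope is biased upward for short windows: measured on iid Gaussian
input (length 4096, 50 seeds) it averages 0.556, because the finite-sample
null expectation E[R/S_n] does not follow the n^0.5 asymptote at small n.
The estimator therefore applies the **Anis–Lloyd/Peters correction** by
default: the regression response is log mean(R/S_n) − log E₀[R/S_n], with
E₀ the closed-form null expectation (gamma-function form for n ≤ 340,
Stirling form above), and H = 0.5 + slope. So corrected, the same null
measurement averages 0.4998 ± 0.02, and Davies–Harte fractional Gaussian
noise of nominal H ∈ {0.3, 0.5, 0.8} is recovered at 0.33/0.49/0.73 — the
familiar residual compression of R/S at the ends of the range, within ±0.1.
`corrected=False` restores the textbook slope.

Classification uses the literal ranges: H < 0.5 anti-persistent, H = 0.5
random, H > 0.5 persistent. Estimates are clipped to [0, 1] with a flag.

## Stationarity

The published analysis used third-party code for its stationarity check;
this package implements the underlying concept directly. The series is cut
into `n_segments = 10` equal blocks; the statistic is the largest
standardized drift of a block mean (scaled by σ/√m) or block variance
(scaled by the normal-theory sd of a sample variance) from the global
value. The threshold is the (1 − α) quantile of the same statistic over 199
seeded random permutations of the samples — an exact reference under the
exchangeable (stationary-iid) null. Linear trends and block-level amplitude
changes are flagged; iid noise is flagged at ≈ the nominal 5% rate.

## Surrogate nonlinearity test

IAAFT surrogates alternate spectral-amplitude substitution with
rank-remapping onto the original sorted values, starting from a seeded
shuffle, until the rank ordering stabilizes (or `max_iter = 100`). The
surrogate conserves the value multiset exactly and matches the power
spectrum to within a few percent.

The default discriminating statistic is the third-order time-reversal
asymmetry mean[(x_{t+τ}−x_t)³]/mean[(x_{t+τ}−x_t)²]^{3/2} at τ = 1 (zero in
expectation for any time-reversible, hence any linear Gaussian, process); a
three-point autocovariance is available by label. The test pools the
observed value with `n_surrogates = 99` surrogate values; with the observed
at ascending rank r among m values, its empirical quantile (r−1)/(m−1) must
fall at or outside α/2 on either side to reject. With 19 surrogates at
α = 0.05 only the extreme ranks reject, which makes the small-ensemble
behavior exact.

## Largest Lyapunov exponent

The series is delay-embedded at (D, τ); each point is paired with its
nearest neighbor at temporal separation greater than a Theiler window
(default: one mean period, from the power-weighted mean frequency of the
spectrum); the mean log separation of the surviving pairs is tracked for
`max_steps` steps; λ₁ is the least-squares slope over the fit range. Exact
duplicate points (distance ≤ 0) are inadmissible as neighbors, and a series
where most points have no admissible neighbor (e.g. a constant) raises.

**Fit range.** The textbook convention fits from step 0 out to one mean
period. On the Lorenz system (dt = 0.01, N = 5000, D = 3, τ = 11) the first
half mean period of the divergence curve has a slope ≈ 2.4/time against a
twin-trajectory (Benettin) oracle value of 0.89: neighbors drawn from
different passes of an oscillatory orbit first separate by phase slippage,
not by the Lyapunov rate. The default fit window is therefore
(min(period/2, max_steps/2), max_steps), which reproduces the oracle within
≈ 10% on Lorenz and stays ≈ 0 on a noiseless sine. Units are per sample;
`lye_per_second` is populated when a frame rate is given. (The study's
printed Lyapunov table does not state its units; no numerical comparison is
attempted beyond the reporting level.)

## Delay and dimension selection

**AMI** uses a 2-D histogram over equiprobable marginal bins (rank-based,
⌊N^{1/3}⌋ bins, floor 8), in nats. Equiprobable binning makes the estimate
exactly symmetric under time reversal (the joint histogram transposes).
The delay criterion is 1/e decay of AMI(0) by default, or the first strict
local minimum. A noiseless sine is a degenerate case: the binned AMI of a
deterministic map fluctuates with bin/phase aliasing and has no clean
quarter-period minimum; with measurement noise the curve is smooth and its
minimum sits at ≈ T/4, but the *strict* first-local-minimum rule is
sensitive to jitter in the flat region — the curve's argmin is the robust
quarter-period diagnostic. When a criterion is never met the maximum lag is
returned with a warning flag. The **global delay** is the rounded (ties
away from zero) mean of the per-coordinate delays, floored at 1.

**FNN** follows Kennel: going from dimension m to m + 1, a nearest neighbor
is false when the added-coordinate distance exceeds `Rtol = 10` times the
m-dimensional distance, or the expanded distance exceeds `Atol = 2` times
the series std. Neighbors closer than 1e−8 × std are skipped as duplicates
(noiseless periodic signals repeat exactly up to floating-point rounding,
and a 0/0 distance ratio is meaningless). Multivariate input is embedded
jointly — each added dimension contributes a delayed copy of all columns —
which is the "global" setting. The selected dimension is the smallest with
FNN ≤ 1%, the usual "FNN drops to about zero" reading; a 10% cutoff would
under-embed (noiseless Lorenz has FNN(2) ≈ 5.9%, and its attractor needs
D = 3). If no dimension qualifies (e.g. pure noise), the argmin is returned
with a warning and `converged=False`.

Note an integer-period sine (period exactly 25 samples) collapses onto a
handful of distinct phase values and degenerates both AMI and FNN;
incommensurate periods are the generic case and are what the tests use.

## Attractor geometry

Convex hulls are computed with qhull. Embeddings with D > 3 are projected
onto their first three delay coordinates before taking the hull — the 3-D
phase portrait one plots and compares — rather than computing
high-dimensional volumes whose magnitudes are not comparable across D;
D = 2 yields an area, D = 1 a range (`dimension_used` records which).
Degenerate (affinely dependent) point sets raise.

**Percentage difference** is |a − b| / min(a, b) × 100 — the smaller value
is the denominator. This is the one convention that reproduces every
printed cell of the study's global-vs-directional difference table from its
recurrence table, and it is used uniformly (hulls included).

## Recurrence quantification

The radius is `radius_fraction = 0.01` of the exact maximum pairwise
distance (O(N²), no bounding-box shortcut; N ≈ 4·10³ is well within reach).
The Heaviside boundary convention is Θ(0) = 1: pairs at exactly distance r
recur. All measures live on the upper triangle with the line of identity
excluded; border-truncated lines count at their observed length.

- REC divides the recurrent upper-triangle cells by N(N−1)/2 so it spans
  0–100%. The printed equation's N² denominator (≈ half the value) is
  available via `rec_normalization="full"`.
- DET = 100 · Σ_{l≥2} l·P(l) / Σ_{l≥1} l·P(l); the denominator equals the
  total recurrent upper-triangle cell count (conservation, asserted in
  tests).
- ENT is the Shannon entropy (nats) of p_l = P(l)/N_l with N_l the number
  of diagonal lines of length ≥ 2, making p a proper distribution.
- LAM and TT use vertical lines within the upper triangle with v_min = 2;
  TT is the mean qualifying vertical-line length.
- Measures with zero denominators are defined as 0.

## Synthetic cohort

The generator emulates the study conditions: 15 subjects, two landmarks,
two tasks, trial lengths uniform in [101, 250] frames at 100 Hz. Each trial
is one smooth turn — θ(t) sweeps 2π under a smoothstep profile, x and z
oscillate as A·sin/cos(θ + φ) under a sin² onset/offset envelope, and y
rises and falls (onto demi-pointe and down) — with task- and
landmark-specific base amplitudes of a few to ~12 cm, per-subject amplitude
factors uniform within ±20%, phase jitter uniform within ±0.3 rad, and iid
Gaussian noise of 2 mm per coordinate (optical-mocap scale). The phase
jitter is deliberately small: every dancer turns through the same 360° from
the same facing, and uniformly random phases would erase the cross-subject
recurrence that the composite construction exists to exploit.

What the generator does *not* emulate: multi-turn pirouettes, anatomical
coupling between landmarks, gap/swap artifacts of real marker data,
task-dependent timing structure within the turn, and the very low
*relative* noise of a laboratory recording — its relative noise (2 mm on
a ~4–12 cm amplitude) exceeds a real lab's, so composite-series REC/DET
sit well below the published 99%+ determinism regime. Passing tests
therefore validate the construction rules, estimator calibration and
measure arithmetic, not the empirical values of the dancer cohort. The
inter-subject effect sizes are conventions, not quantities calibrated to
the original dancers.

## Reporting conventions

Tables are rounded to 2 decimals with **half-up** (ties away from zero)
rounding; the per-task difference table averages the already-rounded
per-row percentage differences. Both conventions were identified by exact
reconstruction of the published aggregates (e.g. a task-mean of 1.775
printed as 1.78; difference-table cells 34.22/3.27 reproducible only from
pre-rounded rows). Zero-valued measure pairs contribute 0 when equal and
are dropped from the mean otherwise. Full precision is retained in the
JSON report. The printed summary tables of the original cohort are bundled
as transcribed CSV fixtures (`pirodyn/data/reference_*.csv`) solely to
exercise this reporting arithmetic; the package never presents them as
computed output.

## Pipeline problem sizes and determinism

The full pipeline estimates embedding parameters on the aligned
pre-reduction composite matrix (the per-coordinate quantile filters keep
different sample subsets, so only the pre-reduction columns are aligned for
the joint "global" estimate), then reduces, embeds, and analyzes each
coordinate in both settings. Every stage seed derives deterministically
from the config seed, and a rerun with the same config is bit-identical.
The default run (15 subjects, ≈ 4050-sample series, 24 embeddings) takes
about half a minute on one core; the test suite exercises the pipeline on
smaller cohorts (3–5 subjects) and the estimators at the lengths quoted
above.

## Known limitations

- The exact procedure by which the original 4500-sample series became 4048
  samples is not recoverable from its description; the deterministic
  quantile filter here yields ≈ 4050 and the two-sample gap is noted, not
  imitated.
- R/S Hurst estimates compress toward 0.5 at the ends of (0, 1) even after
  bias correction; DFA-style estimators are out of scope.
- The Lyapunov fit window is a heuristic over a noisy mean-divergence
  curve; strongly non-stationary composites can still yield unstable fits.
- LAM/TT on the upper triangle only is one of two defensible readings of
  the vertical-line region; the choice is fixed and documented here.
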