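# pirodyn

Nonlinear time-series analysis of repeated motor tasks, built around the
case of single-turn pirouettes (classic and jazz *en dehors*) performed by a
cohort of dancers and recorded by optical motion capture.

A single pirouette yields a short trajectory (one to two hundred frames) for
each landmark — the body's centre of mass (CoM) and the supporting-knee
marker (LKNE) — far too short for state-space reconstruction. `pirodyn`
implements the group-level workaround: the per-subject trials are resampled
to a common length (300 samples), normalized per coordinate by the maximum
absolute value, shuffled into a random subject order, time-reversed at every
second position so consecutive blocks join end-to-end, and concatenated into
one long composite series per coordinate (4500 samples for 15 subjects),
which is then trimmed of its lowest-amplitude samples (below the 10%
quantile). That composite series is treated as one realization of the
group's shared movement dynamics and passed through the standard nonlinear
toolkit:

- **Persistence** — rescaled-range (R/S) Hurst exponent,
  `log E[R/S_n] = H log n + log c`, with the Anis–Lloyd small-sample bias
  correction; H ≈ 0.5 random, H > 0.5 persistent, H < 0.5 anti-persistent.
- **Stationarity** — a windowed-drift statistic on block means/variances
  with a permutation-calibrated threshold.
- **Nonlinearity** — IAAFT surrogate data (exact amplitude distribution,
  matched power spectrum) with a two-sided rank test on a time-reversal
  asymmetry statistic.
- **Chaos** — the largest Lyapunov exponent λ₁ from the divergence of
  nearest neighbors (`d(t) = C·e^{λ₁ t}`, Rosenstein-style).
- **Embedding** — Takens delay coordinates
  `y(t) = (x(t), x(t+τ), …, x(t+(D−1)τ))`, with τ from the average mutual
  information (1/e or first-minimum criterion) and D from Kennel's false
  nearest neighbors; both estimated per coordinate ("directional") or
  jointly from the 3-D trajectory ("global").
- **Attractor geometry** — convex-hull volumes of the embedded trajectories
  (qhull), compared by the percentage difference |a−b|/min(a,b)·100.
- **Recurrence quantification** — `R_{i,j} = Θ(r − ‖x_i − x_j‖)` with r at
  1% of the maximum phase-space diameter, and the six measures REC, DET,
  LMAX, ENT, LAM, TT (line length thresholds `l_min = v_min = 2`, upper
  triangle with the line of identity excluded).

A synthetic cohort generator (quasi-periodic single-turn kinematics with
subject-level amplitude/phase variability and mocap-scale noise) stands in
for the original recordings, which are not redistributable; reference
signals with known dynamics (fractional Gaussian noise, Lorenz, logistic
map, sine) back the estimator tests.

## Worked example

```python
import numpy as np
from pirodyn import (
    generate_pirouette_cohort, prepare_trials, build_composite, quantile_reduce,
    estimate_delay, false_nearest_neighbors, delay_embed,
    recurrence_matrix, rqa_measures, convex_hull_volume, hurst_rs,
)

trials = generate_pirouette_cohort(15, "jazz", "LKNE", (101, 250), noise_sd=0.002, seed=7)
composite = build_composite(prepare_trials(trials), seed=11)
series = quantile_reduce(composite["z"], 0.1)
print(f"composite z: {len(composite['z'])} samples -> {len(series)} after reduction")

delays = estimate_delay(np.column_stack([composite[c].values for c in "xyz"]))
tau = delays.per_column_tau["z"]
fnn = false_nearest_neighbors(composite["z"].values, tau, max_dim=8)
print(f"delay tau = {tau} samples, embedding dimension D = {fnn.selected_D}"
      f" (FNN {fnn.fnn_percentages[fnn.selected_D]:.2f}%)")

emb = delay_embed(series.values, fnn.selected_D, tau)
m = rqa_measures(recurrence_matrix(emb, radius_fraction=0.01))
print(f"REC = {m.rec:.2f}%  DET = {m.det:.2f}%  LMAX = {m.lmax}  "
      f"ENT = {m.ent:.2f}  LAM = {m.lam:.2f}%  TT = {m.tt:.2f}")
print(f"hull volume = {convex_hull_volume(emb).volume:.4f}")
h = hurst_rs(series.values)
print(f"Hurst H = {h.H:.2f} ({h.classification})")
```

prints

```
composite z: 4500 samples -> 4050 after reduction
delay tau = 10 samples, embedding dimension D = 5 (FNN 0.27%)
REC = 0.01%  DET = 12.24%  LMAX = 6  ENT = 0.94  LAM = 13.90%  TT = 2.14
hull volume = 0.2463
Hurst H = 0.68 (persistent)
```

The mediolateral knee series of the synthetic jazz cohort is persistent
(H = 0.68), embeds at D = 5 with a 10-sample delay, and its recurrence plot
shows modest determinism — the synthetic cohort carries proportionally more
marker noise than a real laboratory recording, which depresses REC/DET
relative to the published regime (see `docs/methods.md`).

The same analysis end-to-end, with summary tables written to disk:

```sh
pirodyn run --seed 11 --out results/full
```

The reporting layer also ships the summary tables of the original
15-dancer study as transcribed CSV fixtures; `pirodyn.load_reference_tables`
and the `summarize_*` helpers reproduce the printed aggregates (task-mean
Lyapunov exponents 1.64/1.78, grand-mean Hurst 0.72, and the
global-vs-directional percentage-difference table) exactly.

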