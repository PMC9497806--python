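"""Windowed-drift stationarity check.

A series is treated as non-stationary when its block-wise statistical
structure drifts: the series is split into equal segments, and the largest
standardized deviation of a segment mean (or segment variance) from the
global value is compared against a permutation-calibrated threshold.
Permuting the sample order destroys temporal structure while preserving the
amplitude distribution, so the permutation distribution of the same
statistic provides an exact level-alpha reference under the stationary-iid
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ArgumentError


@dataclass
class StationarityResult:
    statistic: float
    threshold: float
    nonstationary: bool
    n_segments: int
    alpha: float = 0.05


def _drift_statistic(x: np.ndarray, n_segments: int) -> float:
    n = x.size
    seg_len = n // n_segments
    segs = x[: seg_len * n_segments].reshape(n_segments, seg_len)
    g_mean = x.mean()
    g_sd = x.std(ddof=1)
    g_var = x.var(ddof=1)
    if g_sd == 0.0:
        return 0.0
    mean_drift = np.abs(segs.mean(axis=1) - g_mean) / (g_sd / np.sqrt(seg_len))
    # variance drift standardized by the normal-theory sd of a sample variance
    var_drift = np.abs(segs.var(axis=1, ddof=1) - g_var) / (g_var * np.sqrt(2.0 / (seg_len - 1)))
    return float(max(mean_drift.max(), var_drift.max()))


def stationarity_test(
    series: np.ndarray,
    n_segments: int = 10,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
) -> StationarityResult:
    """Permutation test for drift of segment means/variances.

    ``nonstationary`` is True when the observed drift statistic exceeds the
    (1 - alpha) quantile of the statistic over ``n_permutations`` random
    reorderings of the samples.
    """
    x = np.asarray(series, dtype=float).ravel()
    if n_segments < 2:
        raise ArgumentError("need at least 2 segments")
    if x.size < 2 * n_segments:
        raise ArgumentError("too few points per segment")
    if x.size // n_segments < 3:
        raise ArgumentError("segments too short for a variance estimate")
    observed = _drift_statistic(x, n_segments)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_stats[i] = _drift_statistic(rng.permutation(x), n_segments)
    threshold = float(np.quantile(perm_stats, 1.0 - alpha, method="higher"))
    return StationarityResult(
        statistic=observed,
        threshold=threshold,
        nonstationary=bool(observed > threshold),
        n_segments=n_segments,
        alpha=alpha,
    )
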