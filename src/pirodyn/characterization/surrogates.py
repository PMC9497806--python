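"""IAAFT surrogate data and the nonlinearity rank test.

The null hypothesis is that the series is a realization of a linear
Gaussian stochastic process (possibly measured through a static monotone
nonlinearity).  Iterative amplitude-adjusted Fourier transform (IAAFT)
surrogates share the original's amplitude distribution exactly (same sorted
values) and match its power spectrum to convergence tolerance; a
discriminating statistic that differs significantly between the original
and an ensemble of surrogates rejects the null, indicating nonlinear
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ArgumentError

STATISTICS = ("time_reversal_asymmetry", "three_point_autocovariance")


@dataclass
class SurrogateTestResult:
    statistic_name: str
    observed: float
    surrogate_values: np.ndarray
    rank: int
    rejected: bool
    alpha: float
    n_surrogates: int
    params: dict = field(default_factory=dict)


def iaaft_surrogate(
    series: np.ndarray, max_iter: int = 100, seed: int = 0
) -> np.ndarray:
    """One IAAFT surrogate of a 1-D series.

    Alternates (a) replacing the Fourier amplitudes with the original's while
    keeping the current phases and (b) rank-remapping onto the original's
    sorted values, starting from a seeded random shuffle.  Stops when the
    rank ordering stabilizes or after ``max_iter`` iterations.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 16:
        raise ArgumentError("series too short for IAAFT (need >= 16 samples)")
    rng = np.random.default_rng(seed)
    sorted_vals = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = rng.permutation(x)
    prev_ranks = None
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        phase = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phase), n=x.size)
        ranks = np.argsort(np.argsort(s))
        s = sorted_vals[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return s


def time_reversal_asymmetry(x: np.ndarray, lag: int = 1) -> float:
    """Third-order time-reversal asymmetry
    mean[(x_{t+lag} - x_t)^3] / mean[(x_{t+lag} - x_t)^2]^{3/2};
    zero in expectation for any time-reversible (hence any linear Gaussian)
    process."""
    d = x[lag:] - x[:-lag]
    denom = np.mean(d**2) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.mean(d**3) / denom)


def three_point_autocovariance(x: np.ndarray, lag: int = 1) -> float:
    """Normalized three-point autocovariance mean[x_t x_{t+lag} x_{t+2lag}],
    another reversibility-sensitive statistic."""
    z = (x - x.mean()) / x.std()
    return float(np.mean(z[: -2 * lag] * z[lag:-lag] * z[2 * lag :]))


_STAT_FUNCS = {
    "time_reversal_asymmetry": time_reversal_asymmetry,
    "three_point_autocovariance": three_point_autocovariance,
}


def nonlinearity_test(
    series: np.ndarray,
    n_surrogates: int = 99,
    alpha: float = 0.05,
    statistic: str = "time_reversal_asymmetry",
    lag: int = 1,
    max_iter: int = 100,
    seed: int = 0,
) -> SurrogateTestResult:
    """Two-sided rank test of the observed statistic against IAAFT surrogates.

    The observed value is pooled with the ``n_surrogates`` surrogate values;
    with m = n_surrogates + 1 pooled values and the observed at rank r
    (ascending, 1-based), its empirical quantile is q = (r - 1)/(m - 1) and
    the null is rejected when q <= alpha/2 or q >= 1 - alpha/2.  With 19
    surrogates at alpha = 0.05 this rejects only at the extreme ranks 1
    and 20.
    """
    if n_surrogates < 19:
        raise ArgumentError("need at least 19 surrogates")
    if statistic not in _STAT_FUNCS:
        raise ArgumentError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    x = np.asarray(series, dtype=float).ravel()
    func = _STAT_FUNCS[statistic]
    observed = func(x, lag)
    rng = np.random.default_rng(seed)
    surr_vals = np.empty(n_surrogates)
    for i in range(n_surrogates):
        s = iaaft_surrogate(x, max_iter=max_iter, seed=int(rng.integers(2**31 - 1)))
        surr_vals[i] = func(s, lag)
    pooled = np.concatenate([[observed], surr_vals])
    rank = int(np.sum(pooled <= observed))  # 1-based ascending rank of the observed
    m = n_surrogates + 1
    q = (rank - 1) / (m - 1)
    rejected = bool(q <= alpha / 2.0 or q >= 1.0 - alpha / 2.0)
    return SurrogateTestResult(
        statistic_name=statistic,
        observed=observed,
        surrogate_values=surr_vals,
        rank=rank,
        rejected=rejected,
        alpha=alpha,
        n_surrogates=n_surrogates,
        params={"lag": lag, "max_iter": max_iter, "seed": seed},
    )
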