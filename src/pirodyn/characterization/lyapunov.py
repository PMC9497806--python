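"""Largest Lyapunov exponent by the divergence-of-nearest-neighbors method
(Rosenstein-style).

Nearby state-space trajectories of a chaotic system separate exponentially,
d(t) = C * exp(LyE * t).  The series is delay-embedded, each point is paired
with its nearest neighbor at temporal separation greater than a Theiler
window (default: one mean period), the log separation of each pair is
tracked forward in time, and LyE is the least-squares slope of the averaged
log-divergence curve over the initial fit range.  Positive LyE indicates
chaos; a stable limit cycle gives a slope near zero; a stable fixed point a
negative one.

Units: the returned ``lye`` is per sample; ``lye_per_second`` is populated
when a frame rate (or integration step) is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ArgumentError, DegenerateInputError
from ..embedding import delay_embed


@dataclass
class LyapunovResult:
    lye: float  # per sample
    divergence_curve: np.ndarray  # mean log divergence vs step
    fit_range: tuple[int, int]
    D_used: int
    tau_used: int
    theiler: int
    lye_per_second: float | None = None


def mean_period(series: np.ndarray) -> float:
    """Mean period in samples, from the power-weighted mean frequency of the
    (detrended) power spectrum."""
    x = np.asarray(series, dtype=float).ravel()
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    total = power[1:].sum()
    if total == 0.0:
        raise DegenerateInputError("constant series has no mean period")
    mean_freq = float(np.sum(freqs[1:] * power[1:]) / total)
    return 1.0 / mean_freq


def _nearest_neighbors(points: np.ndarray, theiler: int) -> np.ndarray:
    """Index of each point's nearest neighbor with |i - j| > theiler and
    strictly positive distance; -1 where none exists.  Chunked brute force."""
    n = points.shape[0]
    nn = np.full(n, -1, dtype=int)
    chunk = max(1, int(2**22 // max(n, 1)))
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = points[start:stop]
        d2 = np.sum((block[:, None, :] - points[None, :, :]) ** 2, axis=2)
        rows = np.arange(start, stop)
        mask = np.abs(rows[:, None] - idx[None, :]) <= theiler
        d2[mask] = np.inf
        d2[d2 <= 0.0] = np.inf  # exact duplicates carry no divergence information
        j = np.argmin(d2, axis=1)
        found = np.isfinite(d2[np.arange(stop - start), j])
        nn[rows[found]] = j[found]
    return nn


def rosenstein_lye(
    series: np.ndarray,
    D: int,
    tau: int,
    theiler: int | None = None,
    max_steps: int = 100,
    fit_range: tuple[int, int] | None = None,
    frame_rate: float | None = None,
) -> LyapunovResult:
    """Estimate the largest Lyapunov exponent of a scalar series.

    ``theiler`` defaults to the series' mean period (rounded).  ``fit_range``
    defaults to (min(mean period / 2, max_steps / 2), max_steps): the first
    half mean period of the divergence curve is excluded from the fit because
    nearest neighbors drawn from different passes of an oscillatory orbit
    separate super-exponentially at first (phase slippage between loops)
    before settling onto the Lyapunov rate.
    """
    x = np.asarray(series, dtype=float).ravel()
    if D < 1 or tau < 1:
        raise ArgumentError("D and tau must be >= 1")
    emb = delay_embed(x, D, tau)
    points = emb.points
    n = points.shape[0]
    if n < max_steps + 2:
        raise ArgumentError("embedded series too short for the requested max_steps")
    period = mean_period(x)
    if theiler is None:
        theiler = int(round(period))
    nn = _nearest_neighbors(points, theiler)
    valid = nn >= 0
    if valid.sum() < 0.5 * n:
        raise DegenerateInputError("no admissible nearest neighbor for most points")
    i_idx = np.nonzero(valid)[0]
    j_idx = nn[valid]
    curve = np.full(max_steps + 1, np.nan)
    for k in range(max_steps + 1):
        keep = (i_idx + k < n) & (j_idx + k < n)
        if keep.sum() < 2:
            break
        d = np.linalg.norm(points[i_idx[keep] + k] - points[j_idx[keep] + k], axis=1)
        d = d[d > 0.0]
        if d.size < 2:
            continue
        curve[k] = np.mean(np.log(d))
    if fit_range is None:
        fit_range = (int(min(round(period / 2), max_steps // 2)), max_steps)
    lo, hi = fit_range
    if not 0 <= lo < hi <= max_steps:
        raise ArgumentError("fit_range must lie within the divergence curve")
    steps = np.arange(lo, hi + 1)
    seg = curve[lo : hi + 1]
    ok = np.isfinite(seg)
    if ok.sum() < 3:
        raise DegenerateInputError("divergence curve too sparse to fit")
    slope = float(np.polyfit(steps[ok], seg[ok], 1)[0])
    return LyapunovResult(
        lye=slope,
        divergence_curve=curve,
        fit_range=(lo, hi),
        D_used=D,
        tau_used=tau,
        theiler=theiler,
        lye_per_second=slope * frame_rate if frame_rate else None,
    )
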