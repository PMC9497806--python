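"""Delay-coordinate embedding and its two parameters.

A scalar series x(t) is unfolded into state-space vectors

    y(t) = (x(t), x(t + tau), ..., x(t + (D - 1) tau))

with the delay tau chosen from the average mutual information (AMI) curve
(first drop below AMI(0)/e, or first local minimum) and the dimension D from
the false-nearest-neighbors (FNN) criterion of Kennel.  Both parameters can
be estimated per coordinate axis ("directional") or jointly from the full
3-D trajectory ("global"): the global delay is the rounded mean of the
per-axis delays, and global FNN embeds all axes together, as one would for
the Lorenz system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ArgumentError, DegenerateInputError

DELAY_CRITERIA = ("one_over_e", "first_minimum")


@dataclass
class DelayEstimate:
    per_column_tau: dict[str, int]
    global_tau: int
    ami_curves: dict[str, np.ndarray]
    criterion: str = "one_over_e"
    warnings: dict[str, bool] = field(default_factory=dict)


@dataclass
class DimensionEstimate:
    fnn_percentages: dict[int, float]  # dimension -> % false neighbors
    selected_D: int
    mode: str  # "global" or "directional"
    threshold: float = 1.0
    converged: bool = True  # False when no dimension met the threshold


@dataclass
class EmbeddedTrajectory:
    points: np.ndarray  # N_emb x D
    D: int
    tau: int
    source_length: int
    mode: str = "directional"

    def __post_init__(self) -> None:
        expected = self.source_length - (self.D - 1) * self.tau
        if self.points.shape != (expected, self.D):
            raise ArgumentError("embedded point matrix has inconsistent shape")


def average_mutual_information(
    series: np.ndarray, max_lag: int = 100, n_bins: int | None = None
) -> np.ndarray:
    """AMI (in nats) between x(t) and x(t + lag) for lag = 0..max_lag.

    Uses a 2-D histogram over equiprobable marginal bins (each value is
    assigned to a bin by rank), with bin count floor(N^(1/3)) but at least 8
    by default.  Equiprobable bins make the estimate exactly symmetric under
    time reversal.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= max_lag + 1:
        raise ArgumentError("series must be longer than max_lag + 1")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant series carries zero information")
    if n_bins is None:
        n_bins = max(8, int(np.floor(n ** (1.0 / 3.0))))
    # rank-based equiprobable binning of the full series
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    bins = (ranks * n_bins) // n
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = bins[: n - lag]
        b = bins[lag:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        outer = np.outer(px, py)
        ami[lag] = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return ami


def select_delay(ami: np.ndarray, criterion: str = "one_over_e") -> tuple[int, bool]:
    """Pick the delay from an AMI curve.

    ``one_over_e``: the smallest lag with AMI(lag) < AMI(0)/e.
    ``first_minimum``: the smallest lag that is a strict local minimum.
    Returns ``(lag, met)``; when the criterion is never met the maximum lag
    is returned with ``met=False`` and a warning.
    """
    ami = np.asarray(ami, dtype=float)
    if ami.size < 2:
        raise ArgumentError("AMI curve must have at least 2 points")
    if criterion not in DELAY_CRITERIA:
        raise ArgumentError(f"unknown criterion {criterion!r}")
    max_lag = ami.size - 1
    if criterion == "one_over_e":
        threshold = ami[0] / np.e
        below = np.nonzero(ami < threshold)[0]
        below = below[below >= 1]
        if below.size:
            return int(below[0]), True
    else:
        for lag in range(1, max_lag):
            if ami[lag] < ami[lag - 1] and ami[lag] < ami[lag + 1]:
                return lag, True
    warnings.warn(f"delay criterion {criterion!r} never met; returning max lag {max_lag}")
    return max_lag, False


def global_delay(per_column_tau: dict[str, int]) -> int:
    """Arithmetic mean of the per-axis delays, rounded to the nearest integer
    with ties away from zero, floored at 1."""
    if not per_column_tau:
        raise ArgumentError("need at least one per-column delay")
    mean = float(np.mean(list(per_column_tau.values())))
    rounded = int(np.floor(mean + 0.5))  # .5 rounds away from zero (values are positive)
    return max(1, rounded)


def estimate_delay(
    data: np.ndarray,
    max_lag: int = 100,
    criterion: str = "one_over_e",
    n_bins: int | None = None,
    columns: tuple[str, ...] = ("x", "y", "z"),
) -> DelayEstimate:
    """AMI-based delay estimation for a 1-D series or an n x c trajectory."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        columns = columns[:1]
    per_tau: dict[str, int] = {}
    curves: dict[str, np.ndarray] = {}
    warns: dict[str, bool] = {}
    for j in range(arr.shape[1]):
        name = columns[j] if j < len(columns) else str(j)
        curve = average_mutual_information(arr[:, j], max_lag=max_lag, n_bins=n_bins)
        lag, met = select_delay(curve, criterion)
        per_tau[name] = lag
        curves[name] = curve
        warns[name] = not met
    return DelayEstimate(
        per_column_tau=per_tau,
        global_tau=global_delay(per_tau),
        ami_curves=curves,
        criterion=criterion,
        warnings=warns,
    )


def _multi_embed(arr: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Joint delay embedding of an n x c array at embedding copies m:
    rows are (u(t), u(t + tau), ..., u(t + (m-1) tau)) with u the c-vector."""
    n = arr.shape[0]
    rows = n - (m - 1) * tau
    if rows < 2:
        raise ArgumentError("series too short to embed at this dimension")
    return np.hstack([arr[k * tau : k * tau + rows] for k in range(m)])


def false_nearest_neighbors(
    data: np.ndarray,
    tau: int,
    max_dim: int = 10,
    Rtol: float = 10.0,
    Atol: float = 2.0,
    threshold: float = 1.0,
) -> DimensionEstimate:
    """Kennel false-nearest-neighbor percentages over embedding dimension.

    For each dimension m, each point's nearest neighbor (excluding exact
    duplicates) is declared false when the extra coordinates gained at
    m + 1 either inflate the distance by more than ``Rtol`` relative to the
    m-dimensional distance, or push the expanded distance beyond ``Atol``
    times the attractor size (std of the series).  ``selected_D`` is the
    smallest dimension with FNN% <= ``threshold`` (default 1%, the usual
    "FNN drops to about zero" convention); when none qualifies the
    argmin is returned with ``converged=False``.

    1-D input runs the scalar (directional) variant; an n x 3 trajectory is
    embedded jointly (global variant), each added dimension contributing a
    delayed copy of all three axes.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        mode = "directional"
    else:
        mode = "global"
    if tau < 1:
        raise ArgumentError("tau must be >= 1")
    n = arr.shape[0]
    if n - max_dim * tau < 10:
        raise ArgumentError("series too short for FNN at max_dim")
    scale = float(np.std(arr))
    if scale == 0.0:
        raise DegenerateInputError("constant input has no neighbors to classify")
    fnn: dict[int, float] = {}
    for m in range(1, max_dim + 1):
        emb_m = _multi_embed(arr, m, tau)
        emb_m1 = _multi_embed(arr, m + 1, tau)
        rows = emb_m1.shape[0]  # points that survive embedding at m+1
        pts = emb_m[:rows]
        nbrs = NearestNeighbors(n_neighbors=min(len(pts), 8)).fit(pts)
        dist, ind = nbrs.kneighbors(pts)
        # distances at/below this are duplicates (e.g. exact periodic repeats
        # up to floating-point rounding) and carry no expansion information
        dup_tol = 1e-8 * scale
        n_false = 0
        n_total = 0
        for i in range(rows):
            j = -1
            d_m = 0.0
            for cand, dd in zip(ind[i], dist[i]):
                if cand != i and dd > dup_tol:
                    j, d_m = int(cand), float(dd)
                    break
            if j < 0:
                continue
            extra = np.linalg.norm(emb_m1[i, -arr.shape[1]:] - emb_m1[j, -arr.shape[1]:])
            d_m1 = np.hypot(d_m, extra)
            n_total += 1
            if extra / d_m > Rtol or d_m1 / scale > Atol:
                n_false += 1
        fnn[m] = 100.0 * n_false / n_total if n_total else 0.0
    qualifying = [m for m, p in fnn.items() if p <= threshold]
    if qualifying:
        selected = min(qualifying)
        converged = True
    else:
        selected = min(fnn, key=fnn.get)
        converged = False
        warnings.warn("FNN never fell below threshold; returning argmin dimension")
    return DimensionEstimate(
        fnn_percentages=fnn,
        selected_D=selected,
        mode=mode,
        threshold=threshold,
        converged=converged,
    )


def delay_embed(series: np.ndarray, D: int, tau: int, mode: str = "directional") -> EmbeddedTrajectory:
    """Build the delay-embedded trajectory of a scalar series.

    Row t is (x(t), x(t + tau), ..., x(t + (D - 1) tau)); there are
    N - (D - 1) tau rows.
    """
    x = np.asarray(series, dtype=float).ravel()
    if D < 1 or tau < 1:
        raise ArgumentError("D and tau must be >= 1")
    n = x.size
    rows = n - (D - 1) * tau
    if rows < 1:
        raise ArgumentError(f"series of length {n} cannot be embedded with D={D}, tau={tau}")
    points = np.column_stack([x[k * tau : k * tau + rows] for k in range(D)])
    return EmbeddedTrajectory(points=points, D=D, tau=tau, source_length=n, mode=mode)
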