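"""Recurrence matrices and recurrence quantification analysis.

A state-space trajectory x_1..x_N recurs when two points fall within a
radius r of each other:

    R_{i,j} = Theta(r - ||x_i - x_j||),   Theta(u) = 1 for u >= 0

with the Euclidean norm and r fixed at 1% of the maximum phase-space
diameter.  The plot is symmetric about the line of identity (LOI, the main
diagonal), so all measures are computed on the upper triangle with the LOI
excluded:

    REC  — % of recurrent cells,
    DET  — % of recurrent cells on diagonal lines of length >= l_min,
    LMAX — longest diagonal line,
    ENT  — Shannon entropy (nats) of the diagonal line-length distribution,
    LAM  — % of recurrent cells on vertical lines of length >= v_min,
    TT   — mean vertical line (trapping) length,

with l_min = v_min = 2.  Measures whose denominator vanishes are defined
as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedTrajectory
from .errors import ArgumentError, DegenerateInputError


@dataclass
class RecurrenceMatrix:
    indicator: np.ndarray  # N x N uint8, symmetric, unit diagonal
    radius: float
    N: int
    norm: str = "euclidean"
    radius_rule: str = "fraction_of_max_diameter"
    radius_fraction: float = 0.01


@dataclass
class LineHistograms:
    diagonal: dict[int, int]  # length -> count, upper triangle, LOI excluded
    vertical: dict[int, int]
    region: str = "upper_triangle_loi_excluded"


@dataclass
class RQAMeasures:
    rec: float
    det: float
    lmax: int
    ent: float
    lam: float
    tt: float
    l_min: int = 2
    v_min: int = 2
    rec_normalization: str = "upper_triangle"


def recurrence_matrix(
    points: EmbeddedTrajectory | np.ndarray, radius_fraction: float = 0.01
) -> RecurrenceMatrix:
    """Threshold the pairwise Euclidean distances at ``radius_fraction`` of
    the exact maximum phase-space diameter.

    Boundary convention: points at exactly distance r are recurrent
    (Theta(0) = 1).
    """
    arr = points.points if isinstance(points, EmbeddedTrajectory) else np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if n < 2:
        raise ArgumentError("need at least 2 points")
    if radius_fraction <= 0:
        raise ArgumentError("radius_fraction must be positive")
    dist = pdist(arr)  # condensed upper triangle
    diameter = float(dist.max())
    if diameter == 0.0:
        raise DegenerateInputError("all points identical; phase-space diameter is zero")
    r = radius_fraction * diameter
    indicator = (squareform(dist) <= r).astype(np.uint8)
    np.fill_diagonal(indicator, 1)
    return RecurrenceMatrix(indicator=indicator, radius=r, N=n, radius_fraction=radius_fraction)


def _run_lengths(binary: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D 0/1 array."""
    if binary.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate([[0], binary.astype(np.int8), [0]])
    d = np.diff(padded)
    return np.nonzero(d == -1)[0] - np.nonzero(d == 1)[0]


def line_histograms(rm: RecurrenceMatrix) -> LineHistograms:
    """Histograms of diagonal and vertical line lengths in the upper triangle.

    Diagonal lines are maximal runs of ones along each super-diagonal
    (offset >= 1); vertical lines are maximal runs within each column
    restricted to rows above the LOI.  Runs truncated by the matrix border
    count at their observed length.
    """
    R = rm.indicator
    n = rm.N
    diag: Counter[int] = Counter()
    for k in range(1, n):
        for length in _run_lengths(np.diagonal(R, offset=k)):
            diag[int(length)] += 1
    vert: Counter[int] = Counter()
    for j in range(1, n):
        for length in _run_lengths(R[:j, j]):
            vert[int(length)] += 1
    return LineHistograms(diagonal=dict(diag), vertical=dict(vert))


def rqa_measures(
    rm: RecurrenceMatrix,
    hist: LineHistograms | None = None,
    l_min: int = 2,
    v_min: int = 2,
    rec_normalization: str = "upper_triangle",
) -> RQAMeasures:
    """The six recurrence measures from a matrix and its line histograms.

    ``rec_normalization`` divides the recurrent-cell count by the upper
    triangle size N(N-1)/2 (default, so REC spans 0–100%) or by N^2
    (``"full"``, the literal all-cells normalization, smaller by a factor
    of about two).
    """
    if hist is None:
        hist = line_histograms(rm)
    if rec_normalization not in ("upper_triangle", "full"):
        raise ArgumentError("rec_normalization must be 'upper_triangle' or 'full'")
    n = rm.N
    upper = np.triu(rm.indicator, k=1)
    recurrent = int(upper.sum())
    denom = n * (n - 1) / 2.0 if rec_normalization == "upper_triangle" else float(n * n)
    rec = 100.0 * recurrent / denom

    dlen = np.array(sorted(hist.diagonal), dtype=int)
    dcnt = np.array([hist.diagonal[int(l)] for l in dlen], dtype=float)
    total_pts = float(np.sum(dlen * dcnt))  # = all recurrent upper-triangle cells
    long_mask = dlen >= l_min
    det = 100.0 * float(np.sum(dlen[long_mask] * dcnt[long_mask])) / total_pts if total_pts else 0.0
    lmax = int(dlen.max()) if dlen.size else 0

    n_lines = float(np.sum(dcnt[long_mask]))
    if n_lines:
        p = dcnt[long_mask] / n_lines
        ent = float(max(-np.sum(p * np.log(p)), 0.0))
    else:
        ent = 0.0

    vlen = np.array(sorted(hist.vertical), dtype=int)
    vcnt = np.array([hist.vertical[int(v)] for v in vlen], dtype=float)
    vtotal = float(np.sum(vlen * vcnt))
    vmask = vlen >= v_min
    lam = 100.0 * float(np.sum(vlen[vmask] * vcnt[vmask])) / vtotal if vtotal else 0.0
    v_lines = float(np.sum(vcnt[vmask]))
    tt = float(np.sum(vlen[vmask] * vcnt[vmask]) / v_lines) if v_lines else 0.0

    return RQAMeasures(rec=rec, det=det, lmax=lmax, ent=ent, lam=lam, tt=tt,
                       l_min=l_min, v_min=v_min, rec_normalization=rec_normalization)


def analyze(points: EmbeddedTrajectory | np.ndarray, radius_fraction: float = 0.01,
            l_min: int = 2, v_min: int = 2) -> RQAMeasures:
    """Convenience: matrix + histograms + measures in one call."""
    rm = recurrence_matrix(points, radius_fraction)
    return rqa_measures(rm, line_histograms(rm), l_min=l_min, v_min=v_min)


def export_sparse(rm: RecurrenceMatrix, path: str | Path) -> None:
    """Write the recurrent (i, j) coordinate pairs of the upper triangle as text."""
    i, j = np.nonzero(np.triu(rm.indicator, k=1))
    with Path(path).open("w") as fh:
        fh.write("i,j\n")
        for a, b in zip(i, j):
            fh.write(f"{a},{b}\n")


def plot_recurrence(rm: RecurrenceMatrix, path: str | Path, title: str = "") -> None:
    """Save the recurrence plot (recurrent points black) as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(1 - rm.indicator, cmap="gray", origin="lower", interpolation="none")
    ax.set_xlabel("time index j")
    ax.set_ylabel("time index i")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
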