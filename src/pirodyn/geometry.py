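"""Attractor geometry: convex-hull volumes and their comparison.

The convex hull of an embedded trajectory is the smallest convex set
enclosing all its points; its volume summarizes the spatial extent of the
reconstructed attractor and lets phase spaces be compared across tasks and
coordinates.  Hulls are evaluated in at most three dimensions: embeddings
with D > 3 are projected onto their first three delay coordinates (the
3-D phase portraits one actually plots), D = 2 yields an area and D = 1 a
range, recorded in ``dimension_used``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .embedding import EmbeddedTrajectory
from .errors import ArgumentError, DegenerateInputError


@dataclass
class HullSummary:
    volume: float
    n_vertices: int
    dimension_used: int
    source: dict = field(default_factory=dict)


def convex_hull_volume(points: EmbeddedTrajectory | np.ndarray, source: dict | None = None) -> HullSummary:
    """Volume (or area/range in lower dimension) of the convex hull of an
    embedded point cloud."""
    if isinstance(points, EmbeddedTrajectory):
        arr = points.points
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.shape[1] > 3:
        arr = arr[:, :3]
    dim = arr.shape[1]
    if arr.shape[0] < dim + 1:
        raise DegenerateInputError("need at least dimension + 1 points for a hull")
    if dim == 1:
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            raise DegenerateInputError("all points identical; hull is degenerate")
        return HullSummary(volume=float(hi - lo), n_vertices=2, dimension_used=1,
                           source=source or {})
    try:
        hull = ConvexHull(arr)
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate (affinely dependent) point set: {exc}") from exc
    return HullSummary(
        volume=float(hull.volume),
        n_vertices=int(hull.vertices.size),
        dimension_used=dim,
        source=source or {},
    )


def percentage_difference(a: float, b: float) -> float:
    """Percentage difference of two positive quantities, |a - b| / min(a, b) * 100.

    The smaller value is the denominator, so the result is symmetric and
    reads as "the larger exceeds the smaller by this percent"."""
    if a <= 0 or b <= 0:
        raise ArgumentError("percentage_difference requires strictly positive inputs")
    return abs(a - b) / min(a, b) * 100.0
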