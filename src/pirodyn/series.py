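"""Composite group-level series construction.

Many short trials of the same task do not individually support state-space
reconstruction, so the pipeline builds one long series per coordinate from
the whole cohort: each trial is resampled to a common length (300 samples),
normalized per coordinate by its maximum absolute value, the trials are
shuffled into a random order, every trial at an even position in that order
is time-reversed so consecutive blocks join end-to-end into a loop-like
signal, and the blocks are concatenated.  A final quantile filter removes
the lowest-amplitude samples (below the 10% quantile by default) to damp
impulsive troughs, preserving the temporal order of the survivors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError
from .synthetic import DancerTrial

COORDINATES = ("x", "y", "z")
TARGET_LENGTH = 300


@dataclass
class NormalizedTrial:
    """A trial resampled to the common length and normalized per coordinate."""

    values: np.ndarray  # TARGET_LENGTH x 3
    subject_id: int
    landmark: str
    task: str
    scale_factors: np.ndarray  # the 3 per-column max-abs values divided out

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TARGET_LENGTH, 3):
            raise ArgumentError(f"normalized trial must be {TARGET_LENGTH} x 3")


@dataclass
class CompositeSeries:
    """One coordinate of the concatenated group-level series."""

    coordinate: str
    values: np.ndarray
    n_trials: int
    permutation: list[int]  # subject ids in concatenation order
    flipped_positions: list[int]  # 1-based positions that were time-reversed
    reduced: bool = False
    seed: int = 0
    landmark: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def resample_to_fixed_length(trial: DancerTrial, m: int = TARGET_LENGTH) -> DancerTrial:
    """Resample each coordinate onto ``m`` evenly spaced points by linear interpolation.

    The new abscissae span the original index range exactly, so the first and
    last frames are preserved bit-for-bit.
    """
    n = trial.n_frames
    if n < 2:
        raise ArgumentError("trial must have at least 2 frames to resample")
    if m < 2:
        raise ArgumentError("target length must be >= 2")
    old_t = np.arange(n, dtype=float)
    new_t = np.linspace(0.0, n - 1.0, m)
    frames = np.column_stack([np.interp(new_t, old_t, trial.frames[:, j]) for j in range(3)])
    return DancerTrial(
        subject_id=trial.subject_id,
        landmark=trial.landmark,
        task=trial.task,
        frames=frames,
        frame_rate=trial.frame_rate,
    )


def normalize_by_max(trial: DancerTrial) -> NormalizedTrial:
    """Divide each coordinate by its maximum absolute value.

    After normalization every column attains max |value| = 1.  The trial must
    already be at the common length; resample first.
    """
    if trial.n_frames != TARGET_LENGTH:
        raise ArgumentError(f"normalize_by_max expects a {TARGET_LENGTH}-frame trial; resample first")
    scales = np.max(np.abs(trial.frames), axis=0)
    if np.any(scales == 0.0):
        dead = [COORDINATES[j] for j in np.nonzero(scales == 0.0)[0]]
        raise DegenerateInputError(f"all-zero coordinate column(s): {dead}")
    return NormalizedTrial(
        values=trial.frames / scales,
        subject_id=trial.subject_id,
        landmark=trial.landmark,
        task=trial.task,
        scale_factors=scales,
    )


def build_composite(trials: list[NormalizedTrial], seed: int = 0) -> dict[str, CompositeSeries]:
    """Shuffle, flip and concatenate normalized trials into one series per coordinate.

    Trials are put into a seeded uniform random order; trials at even 1-based
    positions of that order are time-reversed (so block boundaries meet at
    matching ends and the concatenation closes into a loop); the blocks are
    then concatenated column-wise.  Returns ``{"x": ..., "y": ..., "z": ...}``.
    """
    if not trials:
        raise ArgumentError("need at least one trial")
    landmarks = {t.landmark for t in trials}
    tasks = {t.task for t in trials}
    if len(landmarks) > 1 or len(tasks) > 1:
        raise ArgumentError(f"mixed landmarks/tasks: {sorted(landmarks)}, {sorted(tasks)}")
    landmark = next(iter(landmarks))
    task = next(iter(tasks))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    permutation = [trials[i].subject_id for i in order]
    flipped = [pos for pos in range(1, len(trials) + 1) if pos % 2 == 0]
    blocks = []
    for pos, i in enumerate(order, start=1):
        block = trials[i].values
        blocks.append(block[::-1] if pos % 2 == 0 else block)
    stacked = np.vstack(blocks)
    return {
        coord: CompositeSeries(
            coordinate=coord,
            values=stacked[:, j].copy(),
            n_trials=len(trials),
            permutation=permutation,
            flipped_positions=flipped,
            reduced=False,
            seed=seed,
            landmark=landmark,
            task=task,
        )
        for j, coord in enumerate(COORDINATES)
    }


def quantile_reduce(series: CompositeSeries, p_low: float = 0.1) -> CompositeSeries:
    """Drop samples strictly below the empirical ``p_low`` quantile.

    The quantile is the linear-interpolation (type-7) empirical quantile of
    the series values.  Survivors keep their temporal order; samples exactly
    at the threshold are retained, so an all-equal series passes unchanged
    and ``p_low = 0`` is the identity.
    """
    if series.reduced:
        raise ArgumentError("series has already been quantile-reduced")
    if not 0.0 <= p_low < 1.0:
        raise ArgumentError("p_low must lie in [0, 1)")
    threshold = np.quantile(series.values, p_low)  # type-7 / linear
    keep = series.values >= threshold
    if keep.sum() < 2:
        raise DegenerateInputError("quantile reduction would leave fewer than 2 samples")
    return CompositeSeries(
        coordinate=series.coordinate,
        values=series.values[keep],
        n_trials=series.n_trials,
        permutation=list(series.permutation),
        flipped_positions=list(series.flipped_positions),
        reduced=True,
        seed=series.seed,
        landmark=series.landmark,
        task=series.task,
    )


# --- file round-trip -------------------------------------------------------

def read_trial_csv(
    path: str | Path, subject_id: int | None = None, landmark: str = "", task: str = ""
) -> DancerTrial:
    """Read a trial CSV/TSV with columns ``frame,x,y,z`` (as written by the generator).

    Metadata missing from the arguments is recovered from the
    ``<task>_<landmark>_S<subject_id>`` filename pattern when it matches.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ArgumentError(f"{path}: missing columns {sorted(missing)}")
    stem_parts = path.stem.split("_")
    if len(stem_parts) == 3 and stem_parts[2].startswith("S"):
        task = task or stem_parts[0]
        landmark = landmark or stem_parts[1]
        if subject_id is None:
            try:
                subject_id = int(stem_parts[2][1:])
            except ValueError:
                subject_id = None
    return DancerTrial(
        subject_id=0 if subject_id is None else subject_id,
        landmark=landmark,
        task=task,
        frames=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def read_cohort(directory: str | Path, landmark: str, task: str) -> list[DancerTrial]:
    """Read every ``<task>_<landmark>_S*.csv`` trial in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{task}_{landmark}_S*.csv"),
                   key=lambda p: int(p.stem.split("_S")[-1]))
    if not paths:
        raise ArgumentError(f"no {task}/{landmark} trial files in {directory}")
    return [read_trial_csv(p) for p in paths]


def prepare_trials(trials: list[DancerTrial]) -> list[NormalizedTrial]:
    """Resample and normalize raw trials — the standard preprocessing chain."""
    return [normalize_by_max(resample_to_fixed_length(t)) for t in trials]


def write_composite(series: CompositeSeries, csv_path: str | Path) -> None:
    """Write a composite series as ``index,value`` CSV plus a JSON sidecar.

    The sidecar (same path with ``.json`` suffix) records the shuffle
    permutation, flipped positions, seed, and reduction flag so that a run
    can be reproduced exactly.
    """
    csv_path = Path(csv_path)
    pd.DataFrame({"index": np.arange(len(series)), "value": series.values}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "coordinate": series.coordinate,
        "n_trials": series.n_trials,
        "permutation": series.permutation,
        "flipped_positions": series.flipped_positions,
        "reduced": series.reduced,
        "seed": series.seed,
        "landmark": series.landmark,
        "task": series.task,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_composite(csv_path: str | Path) -> CompositeSeries:
    csv_path = Path(csv_path)
    values = pd.read_csv(csv_path)["value"].to_numpy(dtype=float)
    sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return CompositeSeries(
        coordinate=meta.get("coordinate", ""),
        values=values,
        n_trials=meta.get("n_trials", 0),
        permutation=meta.get("permutation", []),
        flipped_positions=meta.get("flipped_positions", []),
        reduced=meta.get("reduced", False),
        seed=meta.get("seed", 0),
        landmark=meta.get("landmark", ""),
        task=meta.get("task", ""),
    )
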