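"""End-to-end orchestration and summary reporting.

``run_full_analysis`` chains the stages for every (landmark, task)
combination: cohort input (synthetic or read from disk) -> composite series
construction -> persistence/chaos characterization -> delay embedding in
global and directional settings -> convex-hull geometry -> recurrence
quantification -> summary tables.  The tables mirror the study layout: a
Hurst table and a Lyapunov table (task x series), a 12-row RQA table
(landmark x task x coordinate, global ``all*`` and directional ``d*``
columns per measure), the global-vs-directional mean-percentage-difference
table derived from it, and a hull-volume table.

The reporting helpers (``summarize_means``, ``summarize_setting_differences``)
are pure table arithmetic and also run against the bundled reference
summary tables transcribed from the original dancer cohort, whose raw
recordings are not redistributable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import rqa as rqa_mod
from .characterization import hurst_rs, rosenstein_lye, stationarity_test
from .embedding import delay_embed, estimate_delay, false_nearest_neighbors
from .errors import ArgumentError
from .geometry import convex_hull_volume, percentage_difference
from .series import (
    build_composite,
    prepare_trials,
    quantile_reduce,
    read_cohort,
    write_composite,
)
from .synthetic import generate_pirouette_cohort

MEASURES = ("REC", "DET", "LMAX", "ENT", "LAM", "TT")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (the convention of the
    printed tables, where e.g. a mean of 1.775 appears as 1.78)."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    # format first to strip binary floating-point noise around decimal ties
    return float(Decimal(f"{value:.{decimals + 6}f}").quantize(quantum, rounding=ROUND_HALF_UP))
SERIES_COLUMNS = ("LKNEx", "LKNEy", "LKNEz", "CoMx", "CoMy", "CoMz")
_TASK_SUFFIX = {"jazz": "J", "classic": "C"}


@dataclass
class AnalysisConfig:
    """Settings for a full run; every random choice is driven by ``seed``."""

    n_subjects: int = 15
    tasks: tuple[str, ...] = ("classic", "jazz")
    landmarks: tuple[str, ...] = ("CoM", "LKNE")
    length_range: tuple[int, int] = (101, 250)
    noise_sd: float = 0.002
    seed: int = 0
    cohort_dir: str | None = None  # read trial CSVs instead of simulating
    p_low: float = 0.1
    max_lag: int = 100
    max_dim: int = 10
    fnn_threshold: float = 1.0
    radius_fraction: float = 0.01
    l_min: int = 2
    v_min: int = 2
    lye_max_steps: int = 100
    run_stationarity: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "max_lag", "max_dim", "l_min", "v_min", "lye_max_steps"):
            if getattr(self, name) < 1:
                raise ArgumentError(f"{name} must be positive")
        if self.radius_fraction <= 0:
            raise ArgumentError("radius_fraction must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("tasks", "landmarks", "length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SummaryReport:
    hurst_table: pd.DataFrame
    lye_table: pd.DataFrame
    rqa_table: pd.DataFrame
    setting_difference_table: pd.DataFrame
    hull_table: pd.DataFrame
    details: dict = field(default_factory=dict)
    config: AnalysisConfig | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.hurst_table.to_csv(out / "hurst_table.csv")
        self.lye_table.to_csv(out / "lyapunov_table.csv")
        self.rqa_table.to_csv(out / "rqa_table.csv")
        self.setting_difference_table.to_csv(out / "setting_difference_table.csv")
        self.hull_table.to_csv(out / "hull_table.csv")
        payload = {"details": self.details}
        if self.config is not None:
            payload["config"] = asdict(self.config)
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """The bundled cohort summary tables (transcriptions, not computed here):
    ``hurst`` and ``lyapunov`` (task rows x six series columns) and ``rqa``
    (12 series rows x paired global/directional measure columns)."""
    base = resources.files("pirodyn") / "data"
    return {
        "hurst": pd.read_csv(base / "reference_hurst.csv", index_col=0),
        "lyapunov": pd.read_csv(base / "reference_lyapunov.csv", index_col=0),
        "rqa": pd.read_csv(base / "reference_rqa.csv", index_col=0),
    }


def summarize_means(table: pd.DataFrame, rows=None, columns=None, decimals: int = 2) -> float:
    """Arithmetic mean of the selected cells, rounded to ``decimals``."""
    sub = table
    if rows is not None:
        sub = sub.loc[rows if isinstance(rows, (list, tuple)) else [rows]]
    if columns is not None:
        sub = sub[columns if isinstance(columns, (list, tuple)) else [columns]]
    values = sub.to_numpy(dtype=float).ravel()
    if values.size == 0:
        raise ArgumentError("empty selection")
    return round_half_up(float(values.mean()), decimals)


def summarize_setting_differences(rqa_table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean global-vs-directional percentage difference per task and measure.

    For each measure M the table must hold the paired columns ``allM`` and
    ``dM``; for each task (rows suffixed ``_J`` / ``_C``) the entry is the
    mean of |all - d| / min(all, d) * 100 over the task's series rows, with
    each row's percentage rounded to ``decimals`` before averaging and
    half-up rounding throughout (the printed tables' convention).

    Zero-valued measures (possible on degenerate or very clean inputs) are
    handled by convention: a pair of equal zeros contributes 0, a pair with
    exactly one zero has no finite percentage difference and is dropped from
    the mean (NaN when a task has no finite pair at all).
    """
    for m in MEASURES:
        if f"all{m}" not in rqa_table.columns or f"d{m}" not in rqa_table.columns:
            raise ArgumentError(f"rqa_table lacks paired columns for measure {m}")

    def pct(a: float, b: float) -> float:
        if a == b:
            return 0.0
        if a <= 0 or b <= 0:
            return np.nan
        return percentage_difference(a, b)

    out = {}
    for task, suffix in (("Jazz", "_J"), ("Classic", "_C")):
        rows = [r for r in rqa_table.index if r.endswith(suffix)]
        if not rows:
            continue
        cells = {}
        for m in MEASURES:
            vals = [
                round_half_up(p, decimals) if np.isfinite(p) else np.nan
                for p in (
                    pct(float(rqa_table.loc[r, f"all{m}"]), float(rqa_table.loc[r, f"d{m}"]))
                    for r in rows
                )
            ]
            finite = [v for v in vals if np.isfinite(v)]
            cells[m] = round_half_up(float(np.mean(finite)), decimals) if finite else np.nan
        out[task] = cells
    return pd.DataFrame(out).T[list(MEASURES)]


def _subseed(seed: int, *tags: str) -> int:
    """Stable derived seed below 2**31 for a named pipeline stage."""
    h = np.uint32(seed & 0x7FFFFFFF)
    for tag in tags:
        for ch in tag:
            h = np.uint32(h * np.uint32(31) + np.uint32(ord(ch)))
    return int(h & 0x7FFFFFFF)


def _measure_row(all_m: rqa_mod.RQAMeasures, d_m: rqa_mod.RQAMeasures) -> dict[str, float]:
    row = {}
    for m in MEASURES:
        row[f"all{m}"] = getattr(all_m, m.lower())
        row[f"d{m}"] = getattr(d_m, m.lower())
    return row


def run_full_analysis(config: AnalysisConfig) -> SummaryReport:
    """Run the whole pipeline and assemble the summary report.

    Embedding parameters (delay and dimension) are estimated on the aligned
    pre-reduction composite matrix — globally from all three coordinates
    jointly and directionally per coordinate — and every coordinate series
    is then quantile-reduced, embedded in both settings, and passed through
    Hurst/Lyapunov characterization, convex-hull geometry and RQA.
    Deterministic for a fixed config.
    """
    hurst_rows: dict[str, dict[str, float]] = {}
    lye_rows: dict[str, dict[str, float]] = {}
    rqa_rows: dict[str, dict[str, float]] = {}
    hull_rows: dict[str, dict[str, float]] = {}
    details: dict = {}

    for task in config.tasks:
        hurst_rows.setdefault(task, {})
        lye_rows.setdefault(task, {})
        for landmark in config.landmarks:
            stage = f"{landmark}/{task}"
            try:
                if config.cohort_dir:
                    trials = read_cohort(config.cohort_dir, landmark, task)
                else:
                    trials = generate_pirouette_cohort(
                        config.n_subjects,
                        task,
                        landmark,
                        config.length_range,
                        config.noise_sd,
                        seed=_subseed(config.seed, "cohort", task, landmark),
                    )
                prepared = prepare_trials(trials)
                composites = build_composite(
                    prepared, seed=_subseed(config.seed, "shuffle", task, landmark)
                )
                pre_matrix = np.column_stack([composites[c].values for c in "xyz"])

                delays = estimate_delay(pre_matrix, max_lag=config.max_lag)
                global_tau = delays.global_tau
                global_fnn = false_nearest_neighbors(
                    pre_matrix, global_tau, max_dim=config.max_dim,
                    threshold=config.fnn_threshold,
                )
                global_D = global_fnn.selected_D

                combo_details: dict = {
                    "permutation": composites["x"].permutation,
                    "global_tau": global_tau,
                    "global_D": global_D,
                    "per_column_tau": delays.per_column_tau,
                    "global_fnn_pct": global_fnn.fnn_percentages,
                }

                for coord in "xyz":
                    name = f"{landmark}{coord}"
                    reduced = quantile_reduce(composites[coord], config.p_low)
                    x = reduced.values

                    tau_c = delays.per_column_tau[coord]
                    dir_fnn = false_nearest_neighbors(
                        pre_matrix[:, "xyz".index(coord)], tau_c,
                        max_dim=config.max_dim, threshold=config.fnn_threshold,
                    )
                    D_c = dir_fnn.selected_D

                    hres = hurst_rs(x)
                    hurst_rows[task][name] = round(hres.H, 2)
                    lres = rosenstein_lye(x, D=D_c, tau=tau_c, max_steps=config.lye_max_steps)
                    lye_rows[task][name] = round(lres.lye, 4)

                    emb_all = delay_embed(x, global_D, global_tau, mode="global")
                    emb_dir = delay_embed(x, D_c, tau_c, mode="directional")
                    all_m = rqa_mod.analyze(emb_all, config.radius_fraction,
                                            config.l_min, config.v_min)
                    d_m = rqa_mod.analyze(emb_dir, config.radius_fraction,
                                          config.l_min, config.v_min)
                    row_label = f"{name}_{_TASK_SUFFIX.get(task, task[0].upper())}"
                    rqa_rows[row_label] = _measure_row(all_m, d_m)

                    hull_all = convex_hull_volume(emb_all, source={
                        "landmark": landmark, "task": task, "coordinate": coord, "mode": "global"})
                    hull_dir = convex_hull_volume(emb_dir, source={
                        "landmark": landmark, "task": task, "coordinate": coord, "mode": "directional"})
                    hull_rows[row_label] = {
                        "allCHV": hull_all.volume,
                        "dCHV": hull_dir.volume,
                        "pct_diff": percentage_difference(hull_all.volume, hull_dir.volume)
                        if hull_all.volume > 0 and hull_dir.volume > 0 else np.nan,
                    }

                    coord_details = {
                        "directional_tau": tau_c,
                        "directional_D": D_c,
                        "hurst": hres.H,
                        "hurst_class": hres.classification,
                        "lye_per_sample": lres.lye,
                        "reduced_length": int(x.size),
                    }
                    if config.run_stationarity:
                        sres = stationarity_test(
                            x, seed=_subseed(config.seed, "stat", task, landmark, coord)
                        )
                        coord_details["nonstationary"] = sres.nonstationary
                        coord_details["stationarity_statistic"] = sres.statistic
                    combo_details[coord] = coord_details

                details[stage] = combo_details
            except Exception as exc:
                raise type(exc)(f"[stage {stage}] {exc}") from exc

    series_order = [c for c in SERIES_COLUMNS
                    if c[:-1] in config.landmarks]
    hurst_table = pd.DataFrame(hurst_rows).T[series_order]
    lye_table = pd.DataFrame(lye_rows).T[series_order]
    row_order = [f"{s}_{_TASK_SUFFIX.get(t, t[0].upper())}"
                 for t in ("jazz", "classic") if t in config.tasks
                 for s in series_order]
    rqa_table = pd.DataFrame(rqa_rows).T.loc[row_order]
    hull_table = pd.DataFrame(hull_rows).T.loc[row_order]
    diff_table = summarize_setting_differences(rqa_table)

    # internal consistency: the difference table must be re-derivable
    check = summarize_setting_differences(rqa_table)
    assert check.equals(diff_table)

    report = SummaryReport(
        hurst_table=hurst_table,
        lye_table=lye_table,
        rqa_table=rqa_table,
        setting_difference_table=diff_table,
        hull_table=hull_table,
        details=details,
        config=config,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def write_composites(config: AnalysisConfig, out_dir: str | Path) -> None:
    """Build and persist the composite series (CSV + sidecar) for each
    task/landmark/coordinate without running the downstream analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for task in config.tasks:
        for landmark in config.landmarks:
            if config.cohort_dir:
                trials = read_cohort(config.cohort_dir, landmark, task)
            else:
                trials = generate_pirouette_cohort(
                    config.n_subjects, task, landmark, config.length_range,
                    config.noise_sd, seed=_subseed(config.seed, "cohort", task, landmark),
                )
            composites = build_composite(
                prepare_trials(trials), seed=_subseed(config.seed, "shuffle", task, landmark)
            )
            for coord, series in composites.items():
                write_composite(series, out / f"composite_{task}_{landmark}_{coord}.csv")
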