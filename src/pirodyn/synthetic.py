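"""Synthetic kinematics and reference signals.

The cohort generator emulates single-turn pirouette recordings: a group of
dancers, one landmark (body centre of mass ``CoM`` or supporting-knee marker
``LKNE``), one task (``classic`` or ``jazz``), with trial lengths drawn
uniformly from a frame interval.  Each trial is a smooth quasi-periodic turn
— one sinusoidal oscillation in the horizontal (anterior–posterior ``x`` and
mediolateral ``z``) coordinates under a smooth onset/offset envelope, with a
rise-and-fall vertical (``y``) excursion — plus subject-level amplitude and
phase variability and additive Gaussian noise.  Every dancer performs the
same turn from the same facing, so the subject-level phase variability is a
small jitter (not a uniformly random orientation), and the default noise
level (2 mm) matches optical motion-capture marker noise.

Reference signals (sine, white noise, fractional Gaussian noise, Brownian
motion, the Lorenz system, the logistic map) provide ground-truth dynamics
for the estimators downstream: known Hurst exponents, known Lyapunov signs,
known attractor dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ArgumentError

LANDMARKS = ("CoM", "LKNE")
TASKS = ("classic", "jazz")
REFERENCE_KINDS = ("sine", "white_noise", "fgn", "brownian", "lorenz", "logistic")


@dataclass
class DancerTrial:
    """One subject's raw landmark trajectory: an ``n x 3`` coordinate matrix.

    Columns are ordered x (anterior–posterior), y (inferior–superior),
    z (mediolateral); units are arbitrary length units.
    """

    subject_id: int
    landmark: str
    task: str
    frames: np.ndarray
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ArgumentError("frames must be an n x 3 matrix")
        if not np.all(np.isfinite(self.frames)):
            raise ArgumentError("frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ReferenceSignal:
    """A generated test signal with known dynamics."""

    kind: str
    values: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0


# per-(task, landmark) base amplitudes, in metres-like units:
# (x amplitude, z amplitude, y baseline, y rise amplitude)
_BASE_AMPLITUDES = {
    ("classic", "CoM"): (0.05, 0.04, 1.00, 0.08),
    ("classic", "LKNE"): (0.12, 0.10, 0.50, 0.10),
    ("jazz", "CoM"): (0.06, 0.05, 0.92, 0.05),
    ("jazz", "LKNE"): (0.10, 0.06, 0.45, 0.06),
}


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3.0 - 2.0 * t)


def generate_pirouette_cohort(
    n_subjects: int,
    task: str,
    landmark: str,
    length_range: tuple[int, int] = (101, 250),
    noise_sd: float = 0.002,
    seed: int = 0,
    phase_jitter: float = 0.3,
) -> list[DancerTrial]:
    """Generate a cohort of single-turn pirouette trials.

    Trial lengths are drawn uniformly from ``length_range`` (inclusive on
    both ends).  Each subject gets a random amplitude factor within +/-20%
    of the task/landmark base amplitude, a turn-phase offset uniform in
    +/- ``phase_jitter`` radians, and iid Gaussian noise of standard
    deviation ``noise_sd`` (length units; default 2 mm for metre-scaled
    coordinates) added to every coordinate.  Fully deterministic for a
    fixed seed.
    """
    if n_subjects < 1:
        raise ArgumentError("n_subjects must be >= 1")
    if task not in TASKS:
        raise ArgumentError(f"unknown task {task!r}; expected one of {TASKS}")
    if landmark not in LANDMARKS:
        raise ArgumentError(f"unknown landmark {landmark!r}; expected one of {LANDMARKS}")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 2 or hi < lo:
        raise ArgumentError("length_range must be a non-empty interval within [2, inf)")
    rng = np.random.default_rng(seed)
    ax, az, y0, ay = _BASE_AMPLITUDES[(task, landmark)]
    trials = []
    for sid in range(1, n_subjects + 1):
        n = int(rng.integers(lo, hi + 1))
        amp = 1.0 + rng.uniform(-0.2, 0.2)
        phase = rng.uniform(-phase_jitter, phase_jitter)
        t = np.linspace(0.0, 1.0, n)
        theta = 2.0 * np.pi * _smoothstep(t)  # one full turn, smooth start/stop
        env = np.sin(np.pi * t) ** 2
        x = amp * ax * env * np.sin(theta + phase)
        z = amp * az * env * np.cos(theta + phase)
        y = y0 + amp * ay * np.sin(np.pi * t) ** 2
        frames = np.column_stack([x, y, z])
        frames += rng.normal(0.0, noise_sd, size=frames.shape) if noise_sd > 0 else 0.0
        trials.append(DancerTrial(subject_id=sid, landmark=landmark, task=task, frames=frames))
    return trials


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant (Davies–Harte) embedding."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([gamma[: n + 1], gamma[n - 1 : 0 : -1]])
    m = 2 * n
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        return _fgn_spectral(n, hurst, rng)
    lam = np.clip(lam, 0.0, None)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return np.fft.fft(w).real[:n]


def _fgn_spectral(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    # fallback: shape white noise by the approximate fGn spectrum f^{1-2H}
    freqs = np.fft.rfftfreq(n)
    power = np.ones_like(freqs)
    power[1:] = freqs[1:] ** (0.5 - hurst)
    spectrum = power * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    return (x - x.mean()) / x.std()


def _lorenz(n: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    sigma = float(params.get("sigma", 10.0))
    rho = float(params.get("rho", 28.0))
    beta = float(params.get("beta", 8.0 / 3.0))
    dt = float(params.get("dt", 0.01))
    burn = float(params.get("burn_in", 10.0))

    def rhs(_t, s):
        x, y, z = s
        return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]

    s0 = np.array([1.0, 1.0, 1.0]) + 1e-3 * rng.standard_normal(3)
    t_end = burn + n * dt
    t_eval = burn + dt * np.arange(n)
    sol = solve_ivp(rhs, (0.0, t_end), s0, t_eval=t_eval, rtol=1e-9, atol=1e-9, method="RK45")
    return sol.y.T


def generate_reference_signal(
    kind: str, length: int, params: dict | None = None, seed: int = 0
) -> ReferenceSignal:
    """Generate a reference signal of the requested ``kind``.

    Supported kinds: ``sine`` (A*sin(2*pi*t/period + phase)), ``white_noise``
    (iid standard Gaussian), ``fgn`` (fractional Gaussian noise with Hurst
    parameter ``H_target``, Davies–Harte synthesis), ``brownian`` (cumulative
    sum of white noise), ``lorenz`` (integrated Lorenz system, returns an
    ``n x 3`` trajectory), ``logistic`` (iterates of ``r*x*(1-x)``).
    """
    params = dict(params or {})
    if length < 2:
        raise ArgumentError("length must be >= 2")
    if kind not in REFERENCE_KINDS:
        raise ArgumentError(f"unknown reference kind {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "sine":
        period = float(params.get("period", 25.0))
        amplitude = float(params.get("A", 1.0))
        phase = float(params.get("phase", 0.0))
        t = np.arange(length, dtype=float)
        values = amplitude * np.sin(2.0 * np.pi * t / period + phase)
    elif kind == "white_noise":
        values = rng.standard_normal(length)
    elif kind == "fgn":
        hurst = float(params.get("H_target", 0.5))
        if not 0.0 < hurst < 1.0:
            raise ArgumentError("H_target must lie in (0, 1)")
        values = _fgn_davies_harte(length, hurst, rng)
    elif kind == "brownian":
        values = np.cumsum(rng.standard_normal(length))
    elif kind == "lorenz":
        values = _lorenz(length, params, rng)
    else:  # logistic
        r = float(params.get("r", 4.0))
        x = rng.uniform(0.05, 0.95)
        for _ in range(int(params.get("burn_in", 100))):
            x = r * x * (1.0 - x)
        values = np.empty(length)
        for i in range(length):
            values[i] = x
            x = r * x * (1.0 - x)
    return ReferenceSignal(kind=kind, values=values, params=params, seed=seed)


def trial_filename(trial: DancerTrial) -> str:
    return f"{trial.task}_{trial.landmark}_S{trial.subject_id}.csv"


def write_trial_csv(trial: DancerTrial, path: str | Path) -> None:
    """Write one trial as CSV with columns ``frame,x,y,z`` (6-decimal fixed point)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("frame,x,y,z\n")
        for i, (x, y, z) in enumerate(trial.frames):
            fh.write(f"{i},{x:.6f},{y:.6f},{z:.6f}\n")


def write_cohort(trials: list[DancerTrial], out_dir: str | Path) -> list[Path]:
    """Write every trial of a cohort into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in trials:
        p = out_dir / trial_filename(trial)
        write_trial_csv(trial, p)
        paths.append(p)
    return paths
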