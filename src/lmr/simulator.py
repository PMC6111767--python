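"""Synthetic collar-accelerometer traces with ground-truth annotations.

The generator emulates a home recording of a collar-worn 100 Hz tri-axial
accelerometer on a dog that alternates between three behavioural states:

* Active (Not Resting) — broadband 1-10 Hz movement noise on all axes,
  with the mean gravity direction near the reference (ventral-hang)
  orientation, as a loose collar settles toward gravity in locomotion;
* Resting-Head Up — still, gravity oriented at a ~30 degree head-incline;
* Rest (head-down) — still, head-incline near 0 degrees.

State dwell times are exponential (with a minimum dwell so posture windows
are informative), the head-incline wanders slowly within a state as a
mean-reverting walk, gravity always has unit magnitude before noise,
sensor noise is white, and an optional constant or drifting collar roll is
applied last together with optional Out-of-View annotation gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfilt

from .core import (
    NOT_RESTING,
    REST,
    RESTING_HEAD_UP,
    OUT_OF_VIEW,
    AccelTrace,
    AnnotationTrack,
    ConfigError,
    Interval,
)
from .rotation import rotate_ml_dv

_STATE_LABELS = (NOT_RESTING, RESTING_HEAD_UP, REST)  # active, head-up, head-down


@dataclass
class SimConfig:
    """Study-condition defaults: 100 Hz sampling, 144 min recordings.

    ``collar_rotation_deg`` may be a constant angle or a ``(start, end)``
    pair that drifts linearly over the recording.
    """

    sampling_rate: float = 100.0
    duration_s: float = 8640.0
    dwell_active_s: float = 60.0
    dwell_rest_head_up_s: float = 120.0
    dwell_rest_head_down_s: float = 300.0
    min_dwell_s: float = 20.0
    incline_headup_deg: float = 30.0
    incline_headup_sd_deg: float = 5.0
    incline_headdown_deg: float = 0.0
    incline_headdown_sd_deg: float = 5.0
    incline_active_deg: float = 0.0
    incline_active_sd_deg: float = 10.0
    incline_tau_s: float = 30.0
    incline_active_tau_s: float = 1.0
    active_movement_sd_g: float = 0.2
    rest_movement_sd_g: float = 0.008
    movement_band_hz: tuple[float, float] = (1.0, 10.0)
    sensor_noise_sd_g: float = 0.005
    collar_rotation_deg: float | tuple[float, float] = 0.0
    oov_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "incline_headup_sd_deg",
            "incline_headdown_sd_deg",
            "incline_active_sd_deg",
            "active_movement_sd_g",
            "rest_movement_sd_g",
            "sensor_noise_sd_g",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("dwell_active_s", "dwell_rest_head_up_s", "dwell_rest_head_down_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 <= self.oov_fraction < 1:
            raise ConfigError("oov_fraction must be in [0, 1)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")


def _state_segments(config: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """Semi-Markov alternation with exponential dwells and a minimum dwell."""
    means = {
        NOT_RESTING: config.dwell_active_s,
        RESTING_HEAD_UP: config.dwell_rest_head_up_s,
        REST: config.dwell_rest_head_down_s,
    }
    weights = np.array([means[s] for s in _STATE_LABELS], dtype=float)
    state = _STATE_LABELS[rng.choice(len(_STATE_LABELS), p=weights / weights.sum())]
    segments = []
    t = 0.0
    while t < config.duration_s:
        dwell = max(config.min_dwell_s, rng.exponential(means[state]))
        end = min(t + dwell, config.duration_s)
        segments.append((t, end, state))
        t = end
        others = [s for s in _STATE_LABELS if s != state]
        state = others[rng.integers(len(others))]
    return segments


def _ou_walk(
    n: int,
    mean: float,
    sd: float,
    tau_s: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-reverting incline walk with stationary SD ``sd``, reflected at 90."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, mean)
    from scipy.signal import lfilter

    dt = 1.0 / fs
    alpha = np.exp(-dt / tau_s)
    sigma_step = sd * np.sqrt(1.0 - alpha**2)
    x0 = rng.normal(0.0, sd)
    steps = rng.normal(0.0, sigma_step, size=n - 1)
    # AR(1) recursion x_i = alpha x_{i-1} + step_i, vectorised
    tail, _ = lfilter([1.0], [1.0, -alpha], steps, zi=np.array([alpha * x0]))
    x = mean + np.concatenate([[x0], tail])
    # reflect at +/-90 degrees
    x = np.mod(x + 180.0, 360.0) - 180.0
    x = np.where(x > 90.0, 180.0 - x, x)
    x = np.where(x < -90.0, -180.0 - x, x)
    return x


def _band_noise(
    n: int,
    sd: float,
    band: tuple[float, float],
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise (3 axes) rescaled to the target SD."""
    if n == 0 or sd == 0:
        return np.zeros((n, 3))
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    white = rng.normal(size=(n, 3))
    if n > 30 and hi > lo:
        sos = butter(2, [lo, hi], btype="band", fs=fs, output="sos")
        shaped = sosfilt(sos, white, axis=0)
    else:
        shaped = white
    scale = shaped.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def simulate_dog(config: SimConfig | None = None) -> tuple[AccelTrace, AnnotationTrack]:
    """Generate one labelled recording; deterministic for a fixed seed."""
    config = config or SimConfig()
    if config.duration_s < 10.0:
        raise ConfigError("duration_s must cover at least one 10 s posture window")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_total = int(round(config.duration_s * fs))

    segments = _state_segments(config, rng)

    incline = np.empty(n_total)
    movement = np.zeros((n_total, 3))
    # (mean incline, wander SD, wander timescale, movement SD) per state;
    # resting heads drift slowly, a moving collar sways at gait pace
    state_params = {
        NOT_RESTING: (
            config.incline_active_deg,
            config.incline_active_sd_deg,
            config.incline_active_tau_s,
            config.active_movement_sd_g,
        ),
        RESTING_HEAD_UP: (
            config.incline_headup_deg,
            config.incline_headup_sd_deg,
            config.incline_tau_s,
            config.rest_movement_sd_g,
        ),
        REST: (
            config.incline_headdown_deg,
            config.incline_headdown_sd_deg,
            config.incline_tau_s,
            config.rest_movement_sd_g,
        ),
    }
    for start, end, state in segments:
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n_total)
        n = i1 - i0
        mean, sd, tau, move_sd = state_params[state]
        incline[i0:i1] = _ou_walk(n, mean, sd, tau, fs, rng)
        movement[i0:i1] = _band_noise(n, move_sd, config.movement_band_hz, fs, rng)

    # gravity reading: unit vector at the head-incline angle (head-tilt 0)
    phi = np.deg2rad(incline)
    gravity = np.column_stack([np.zeros(n_total), np.sin(phi), np.cos(phi)])
    samples = gravity + movement + rng.normal(0.0, config.sensor_noise_sd_g, (n_total, 3))

    rho = config.collar_rotation_deg
    if isinstance(rho, (tuple, list)):
        rho = np.linspace(rho[0], rho[1], n_total)
    if np.any(np.asarray(rho) != 0):
        ay, az = rotate_ml_dv(samples[:, 1], samples[:, 2], rho)
        samples = np.column_stack([samples[:, 0], ay, az])

    trace = AccelTrace(
        sampling_rate=fs, ax=samples[:, 0], ay=samples[:, 1], az=samples[:, 2]
    )

    intervals = [Interval(s, e, lab) for s, e, lab in segments]
    intervals.extend(_oov_intervals(config, rng))
    return trace, AnnotationTrack(intervals)


def _oov_intervals(config: SimConfig, rng: np.random.Generator) -> list[Interval]:
    if config.oov_fraction == 0:
        return []
    total = config.oov_fraction * config.duration_s
    chunk = min(30.0, total)
    n_chunks = max(1, int(round(total / chunk)))
    out = []
    for _ in range(n_chunks):
        start = rng.uniform(0.0, max(config.duration_s - chunk, 1e-6))
        out.append(Interval(start, min(start + chunk, config.duration_s), OUT_OF_VIEW))
    return out


def simulate_cohort(
    n_subjects: int,
    config: SimConfig | None = None,
    config_variation: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
) -> list[tuple[AccelTrace, AnnotationTrack]]:
    """Simulate ``n_subjects`` dogs with seeds derived from a master seed.

    ``config_variation`` maps SimConfig field names to additive Gaussian
    jitter SDs applied per subject (clipped to stay positive where the
    field requires it).
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    base = config or SimConfig()
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    variation = config_variation or {}
    out = []
    for i in range(n_subjects):
        overrides: dict = {"seed": int(subject_seeds[i])}
        jitter_rng = np.random.default_rng(int(subject_seeds[i]) ^ 0x5EED)
        for name, sd in variation.items():
            value = getattr(base, name) + jitter_rng.normal(0.0, sd)
            if name.endswith("_g") or name.endswith("_s") or name.endswith("sd_deg"):
                value = max(value, 1e-6)
            overrides[name] = value
        out.append(simulate_dog(replace(base, **overrides)))
    return out
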