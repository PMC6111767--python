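"""Tilt estimation from the gravity vector and head-up/head-down windows.

With the sensor worn ventrally on the collar, pitch maps to head-tilt
(positive tilting left from the dog's perspective) and the mu-stabilised
roll maps to head-incline (positive = head away from the floor).  Head
state is decided by thresholding the mean head-incline over 10 s windows,
which suppresses fast transients such as head-shakes:

    theta = atan( -Ax / sqrt(Ay^2 + Az^2) )
    phi   = atan(  Ay / (sign(Az) * sqrt(Az^2 + mu * Ax^2)) ),  sign(0) = +1

HeadUp is declared when the window mean incline is >= omega (default 14
degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import AccelTrace, ConfigError, InsufficientDataError

HEAD_UP = "HeadUp"
HEAD_DOWN = "HeadDown"


@dataclass
class PostureConfig:
    mu: float = 0.1
    window_length_s: float = 10.0
    omega_deg: float = 14.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConfigError("mu must be > 0")
        if self.window_length_s <= 0:
            raise ConfigError("window_length_s must be > 0")
        if not 0 < self.omega_deg < 90:
            raise ConfigError("omega_deg must be in (0, 90)")


@dataclass
class OrientationSeries:
    """Per-sample pitch (head-tilt) and roll (head-incline) in degrees.

    Samples where the acceleration vector is exactly zero carry NaN.
    """

    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __len__(self) -> int:
        return len(self.roll_deg)


@dataclass
class HeadStateSeries:
    """Per-window head state on contiguous, non-overlapping windows.

    ``hd`` entries are HeadUp/HeadDown, or None for windows with no valid
    orientation samples.
    """

    window_start_s: np.ndarray
    hd: np.ndarray
    window_length_s: float
    omega_deg: float


def _signed(az: np.ndarray) -> np.ndarray:
    """sign() with sign(0) = +1."""
    return np.where(az >= 0, 1.0, -1.0)


def pitch_roll(trace: AccelTrace, config: PostureConfig | None = None) -> OrientationSeries:
    """Per-sample pitch/roll from the gravity direction.

    The stabiliser ``mu`` keeps the roll denominator away from zero when
    the DV reading is small (sensor near edge-on to gravity).
    """
    config = config or PostureConfig()
    ax, ay, az = trace.ax, trace.ay, trace.az
    zero = (ax == 0) & (ay == 0) & (az == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = np.degrees(np.arctan(-ax / np.sqrt(ay**2 + az**2)))
        roll = np.degrees(
            np.arctan(ay / (_signed(az) * np.sqrt(az**2 + config.mu * ax**2)))
        )
    pitch = np.where(zero, np.nan, pitch)
    roll = np.where(zero, np.nan, roll)
    return OrientationSeries(
        pitch_deg=pitch,
        roll_deg=roll,
        sampling_rate=trace.sampling_rate,
        start_time=trace.start_time,
    )


def head_incline_windows(
    orientation: OrientationSeries,
    sampling_rate: float | None = None,
    window_length_s: float = 10.0,
) -> np.ndarray:
    """Mean head-incline per non-overlapping window, NaN samples excluded.

    Windows containing no valid sample come back NaN.  The trailing partial
    window is dropped.
    """
    fs = sampling_rate or orientation.sampling_rate
    n = int(round(fs * window_length_s))
    if n < 1:
        raise ConfigError("window shorter than one sample")
    m = len(orientation) // n
    if m < 1:
        raise InsufficientDataError("fewer samples than one window")
    blocks = np.asarray(orientation.roll_deg[: m * n], dtype=float).reshape(m, n)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(blocks, axis=1)
        counts = np.sum(np.isfinite(blocks), axis=1)
    means = np.full(m, np.nan)
    ok = counts > 0
    means[ok] = sums[ok] / counts[ok]
    return means


def head_state(
    mean_incline: np.ndarray,
    omega_deg: float = 14.0,
    window_length_s: float = 10.0,
    origin_s: float = 0.0,
) -> HeadStateSeries:
    """Threshold window-mean incline: HeadUp iff mean >= omega."""
    mean_incline = np.asarray(mean_incline, dtype=float)
    hd = np.empty(len(mean_incline), dtype=object)
    for i, v in enumerate(mean_incline):
        hd[i] = None if np.isnan(v) else (HEAD_UP if v >= omega_deg else HEAD_DOWN)
    starts = origin_s + window_length_s * np.arange(len(mean_incline))
    return HeadStateSeries(
        window_start_s=starts, hd=hd, window_length_s=window_length_s, omega_deg=omega_deg
    )


class PostureEstimator(BaseEstimator):
    """sklearn-style transformer: trace -> per-window head state."""

    def __init__(
        self, mu: float = 0.1, window_length_s: float = 10.0, omega_deg: float = 14.0
    ):
        self.mu = mu
        self.window_length_s = window_length_s
        self.omega_deg = omega_deg

    def _config(self) -> PostureConfig:
        return PostureConfig(
            mu=self.mu, window_length_s=self.window_length_s, omega_deg=self.omega_deg
        )

    def fit(self, X=None, y=None):
        self._config()
        self.n_features_in_ = 1
        return self

    def transform(self, X: AccelTrace) -> HeadStateSeries:
        orientation = pitch_roll(X, self._config())
        means = head_incline_windows(orientation, X.sampling_rate, self.window_length_s)
        return head_state(
            means, self.omega_deg, self.window_length_s, origin_s=X.start_time
        )

    def fit_transform(self, X: AccelTrace, y=None) -> HeadStateSeries:
        return self.fit(X, y).transform(X)
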