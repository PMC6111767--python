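"""Collar-rotation correction about the cranial-caudal (AP) axis.

A collar-mounted sensor rarely sits precisely ventrally and can rotate
around the neck during wear.  Gravity is the only absolute orientation
reference an accelerometer provides, so the correction isolates the
gravity component with a gentle zero-phase low-pass (0.5 Hz) and measures
the angle of its (ML, DV) projection relative to the reference under-chin
orientation in non-overlapping windows.

Head-incline itself moves gravity in the very same (ML, DV) plane, so the
two must be separated physically rather than per window: during
locomotion a collar-mounted sensor settles toward the bottom of the neck,
i.e. its gravity direction reveals the mounting offset with the head
posture averaged out.  The collar angle is therefore the circular median
over high-movement (locomotion) windows; recordings with under a minute
of movement fall back to the median over all reliable windows, which
instead assumes the dominant sustained posture is head-down recumbency.
The single median angle is applied to every sample so the z axis again
reads dorsal-ventral.

Positive angles mean the collar has rotated toward the dog's left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.base import BaseEstimator

from .core import AccelTrace, ConfigError, DataError, InsufficientDataError


@dataclass
class RotationEstimate:
    """Per-window collar roll angles (degrees, in (-180, 180]).

    ``angle_deg`` holds the correction angle per window (constant — the
    circular median over reliable windows); ``raw_angle_deg`` keeps the
    unsmoothed per-window gravity angles for diagnostics.
    """

    angle_deg: np.ndarray
    window_length_s: float
    reliable: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    raw_angle_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    smoothing: str = "circular median over reliable windows"

    @property
    def n_windows(self) -> int:
        return len(self.angle_deg)

    @property
    def all_unreliable(self) -> bool:
        return not bool(np.any(self.reliable))


def _wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap into (-180, 180]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


def circular_median(angles_deg: np.ndarray) -> float:
    """Median of angles taken after re-centring around the mean direction."""
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise DataError("no angles to take a median of")
    mean_dir = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    centred = np.angle(np.exp(1j * (angles - mean_dir)))
    return float(_wrap_deg(np.rad2deg(mean_dir + np.median(centred))))


def rotate_ml_dv(ay: np.ndarray, az: np.ndarray, angle_deg) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the (ML, DV) pair by ``angle_deg`` about the AP axis."""
    rho = np.deg2rad(angle_deg)
    c, s = np.cos(rho), np.sin(rho)
    return ay * c - az * s, ay * s + az * c


def _gravity(trace: AccelTrace, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass of all axes; rows = samples, cols = (AP, ML, DV)."""
    nyquist = trace.sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ConfigError(f"gravity cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    sos = butter(2, cutoff_hz, btype="low", fs=trace.sampling_rate, output="sos")
    stacked = np.column_stack([trace.ax, trace.ay, trace.az])
    padlen = min(3 * (2 * 2 + 1), trace.n_samples - 1)
    return sosfiltfilt(sos, stacked, axis=0, padlen=padlen)


def estimate_collar_rotation(
    trace: AccelTrace,
    window_length_s: float = 10.0,
    gravity_cutoff_hz: float = 0.5,
    movement_sd_threshold_g: float = 0.05,
    min_locomotion_windows: int = 6,
) -> RotationEstimate:
    """Estimate the collar roll angle from the gravity direction.

    Windows where the low-passed gravity magnitude leaves [0.5, 1.5] g for
    more than half the samples are flagged unreliable and do not vote.
    Among reliable windows, those whose raw magnitude SD exceeds
    ``movement_sd_threshold_g`` count as locomotion: there the hanging
    collar reads the mounting offset directly, free of head-incline, so
    their circular median is the correction angle.  With fewer than
    ``min_locomotion_windows`` such windows the median over all reliable
    windows is used instead (valid when head-down recumbency dominates
    the recording).  If no window is reliable the estimate is zero with an
    all-unreliable flag.
    """
    n = int(round(trace.sampling_rate * window_length_s))
    if n < 1:
        raise ConfigError("window shorter than one sample")
    m = trace.n_samples // n
    if m < 1:
        raise InsufficientDataError("trace shorter than one rotation window")
    grav = _gravity(trace, gravity_cutoff_hz)[: m * n]
    mag = np.linalg.norm(grav, axis=1).reshape(m, n)
    reliable = np.mean((mag >= 0.5) & (mag <= 1.5), axis=1) >= 0.5

    # window-mean gravity reading; reference orientation reads (0, 0, +1)
    mean_g = grav.reshape(m, n, 3).mean(axis=1)
    raw = np.degrees(np.arctan2(-mean_g[:, 1], mean_g[:, 2]))

    raw_mag = trace.magnitude()[: m * n].reshape(m, n)
    moving = raw_mag.std(axis=1, ddof=0) > movement_sd_threshold_g
    voters = reliable & moving
    if np.sum(voters) < min_locomotion_windows:
        voters = reliable
    if voters.any():
        collar = circular_median(raw[voters])
    else:
        collar = 0.0
    return RotationEstimate(
        angle_deg=np.full(m, _wrap_deg(collar), dtype=float),
        window_length_s=window_length_s,
        reliable=reliable,
        raw_angle_deg=np.asarray(_wrap_deg(raw), dtype=float),
    )


def apply_rotation_correction(trace: AccelTrace, estimate: RotationEstimate) -> AccelTrace:
    """Counter-rotate (ML, DV) per sample; AP and per-sample |A| unchanged.

    Window angles are interpolated linearly across window centres (constant
    beyond the first/last centre), so a constant collar offset corrects
    exactly and slow drift corrects smoothly at window joins.
    """
    if estimate.n_windows < 1:
        raise DataError("rotation estimate has no windows")
    fs = trace.sampling_rate
    centers = (np.arange(estimate.n_windows) + 0.5) * estimate.window_length_s
    # unwrap so interpolation never crosses the +/-180 seam the short way
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(estimate.angle_deg)))
    t = np.arange(trace.n_samples) / fs
    per_sample = np.interp(t, centers, unwrapped)
    ay, az = rotate_ml_dv(trace.ay, trace.az, -per_sample)
    return AccelTrace(
        sampling_rate=fs,
        ax=trace.ax.copy(),
        ay=ay,
        az=az,
        start_time=trace.start_time,
        axis_convention=dict(trace.axis_convention),
    )


def rotation_to_csv(estimate: RotationEstimate, path) -> None:
    import pandas as pd

    starts = estimate.window_length_s * np.arange(estimate.n_windows)
    pd.DataFrame(
        {"window_start_s": starts, "angle_deg": estimate.angle_deg}
    ).to_csv(path, index=False, float_format="%.4f")


class CollarRotationCorrector(BaseEstimator):
    """sklearn-style transformer: estimate collar roll, counter-rotate.

    ``fit`` estimates per-window angles from the trace it is given;
    ``transform`` applies the stored estimate.  Use ``fit_transform`` for
    the usual same-trace correction.
    """

    def __init__(
        self,
        window_length_s: float = 10.0,
        gravity_cutoff_hz: float = 0.5,
    ):
        self.window_length_s = window_length_s
        self.gravity_cutoff_hz = gravity_cutoff_hz

    def fit(self, X: AccelTrace, y=None):
        self.estimate_: Optional[RotationEstimate] = estimate_collar_rotation(
            X,
            window_length_s=self.window_length_s,
            gravity_cutoff_hz=self.gravity_cutoff_hz,
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X: AccelTrace) -> AccelTrace:
        if not hasattr(self, "estimate_"):
            raise DataError("CollarRotationCorrector must be fitted before transform")
        return apply_rotation_correction(X, self.estimate_)

    def fit_transform(self, X: AccelTrace, y=None) -> AccelTrace:
        return self.fit(X, y).transform(X)
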