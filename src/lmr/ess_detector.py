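"""Low-movement detection from the dorsal-ventral axis (ESS stage).

The Estimation-of-Stationary-Sleep-Segments (ESS) approach discards the AP
and ML channels, low-pass filters the DV channel (first-order Butterworth,
3 Hz cutoff by default), splits it into non-overlapping 1 s epochs and
declares low movement (L = 1) whenever the epoch's population standard
deviation is at or below a threshold delta (default 0.014 g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter
from sklearn.base import BaseEstimator

from .core import AccelTrace, ConfigError, InsufficientDataError


@dataclass
class FilterConfig:
    """First-order-by-default Butterworth low-pass for the DV channel."""

    cutoff_hz: float = 3.0
    order: int = 1
    design: str = "Butterworth low-pass"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be > 0")
        if self.order < 1:
            raise ConfigError("order must be >= 1")


@dataclass
class LowMovementSeries:
    """Per-epoch binary low-movement flag L plus the epoch SDs behind it."""

    epoch_length_s: float
    values: np.ndarray  # 0/1, one per epoch
    delta_g: float
    epoch_sd: np.ndarray = field(default_factory=lambda: np.empty(0))
    origin_s: float = 0.0

    @property
    def starts(self) -> np.ndarray:
        return self.origin_s + self.epoch_length_s * np.arange(len(self.values))


def lowpass_dv(trace: AccelTrace, config: FilterConfig | None = None) -> np.ndarray:
    """Causal IIR low-pass of the DV channel; AP/ML are discarded."""
    config = config or FilterConfig()
    nyquist = trace.sampling_rate / 2.0
    if config.cutoff_hz >= nyquist:
        raise ConfigError(
            f"cutoff {config.cutoff_hz} Hz >= Nyquist {nyquist} Hz"
        )
    b, a = butter(config.order, config.cutoff_hz, btype="low", fs=trace.sampling_rate)
    return lfilter(b, a, trace.az)


def epoch_sd(
    samples: np.ndarray, sampling_rate: float, epoch_length_s: float = 1.0
) -> np.ndarray:
    """Population (divide-by-n) SD over non-overlapping epochs.

    The trailing partial epoch is dropped.
    """
    n = int(round(sampling_rate * epoch_length_s))
    if n < 1:
        raise ConfigError("epoch shorter than one sample")
    m = len(samples) // n
    if m < 1:
        raise InsufficientDataError("fewer samples than one epoch")
    return np.asarray(samples[: m * n], dtype=float).reshape(m, n).std(axis=1, ddof=0)


def ess_low_movement(
    filtered_dv: np.ndarray,
    sampling_rate: float,
    delta_g: float = 0.014,
    epoch_length_s: float = 1.0,
) -> LowMovementSeries:
    """Per-epoch low-movement prediction: L = 1 iff epoch SD <= delta."""
    if delta_g <= 0:
        raise ConfigError("delta_g must be > 0")
    sd = epoch_sd(filtered_dv, sampling_rate, epoch_length_s)
    return LowMovementSeries(
        epoch_length_s=epoch_length_s,
        values=(sd <= delta_g).astype(int),
        delta_g=delta_g,
        epoch_sd=sd,
    )


class LowMovementDetector(BaseEstimator):
    """sklearn-style transformer wrapping the ESS low-movement stage.

    ``transform`` maps an :class:`~lmr.core.AccelTrace` (rotation-corrected,
    DV on z) to a :class:`LowMovementSeries`.  Stateless; ``fit`` only
    validates parameters.
    """

    def __init__(
        self,
        delta_g: float = 0.014,
        cutoff_hz: float = 3.0,
        order: int = 1,
        epoch_length_s: float = 1.0,
    ):
        self.delta_g = delta_g
        self.cutoff_hz = cutoff_hz
        self.order = order
        self.epoch_length_s = epoch_length_s

    def fit(self, X=None, y=None):
        FilterConfig(cutoff_hz=self.cutoff_hz, order=self.order)
        if self.delta_g <= 0:
            raise ConfigError("delta_g must be > 0")
        self.n_features_in_ = 1
        return self

    def transform(self, X: AccelTrace) -> LowMovementSeries:
        filtered = lowpass_dv(X, FilterConfig(cutoff_hz=self.cutoff_hz, order=self.order))
        return ess_low_movement(
            filtered, X.sampling_rate, self.delta_g, self.epoch_length_s
        )

    def fit_transform(self, X: AccelTrace, y=None) -> LowMovementSeries:
        return self.fit(X, y).transform(X)
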