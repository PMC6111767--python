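"""Hierarchical Low Movement Recumbency (LMR) state classification.

Decision tree per 1 s epoch:

1. movement stage — the ESS detector flags the epoch low-movement (L = 1)
   or not; L = 0 means Active;
2. posture stage — low-movement epochs are split into RestHeadUp /
   RestHeadDown by the mean head-incline of the 10 s window centred on the
   epoch (clamped at trace edges), thresholded at omega.

The posture stage is computed everywhere but consumed only where L = 1, so
no head-state label is ever emitted for an Active epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import (
    ACTIVE,
    REST_HEAD_DOWN,
    REST_HEAD_UP,
    AccelTrace,
    AnnotationTrack,
    ConfigError,
    InsufficientDataError,
    StateSeries,
)
from .ess_detector import FilterConfig, ess_low_movement, lowpass_dv
from .posture import PostureConfig, pitch_roll
from .rotation import CollarRotationCorrector


@dataclass
class Thresholds:
    """The two fitted decision thresholds of the method."""

    delta_g: float = 0.014
    omega_deg: float = 14.0

    def __post_init__(self) -> None:
        if self.delta_g <= 0 or self.omega_deg <= 0:
            raise ConfigError("thresholds must be positive")


def centred_incline_means(
    roll_deg: np.ndarray,
    sampling_rate: float,
    epoch_length_s: float = 1.0,
    window_length_s: float = 10.0,
    n_epochs: Optional[int] = None,
) -> np.ndarray:
    """Mean head-incline over the window centred on each epoch.

    Windows are clamped at the trace edges; NaN orientation samples are
    excluded from the mean.
    """
    n = int(round(sampling_rate * epoch_length_s))
    w = int(round(sampling_rate * window_length_s))
    n_samples = len(roll_deg)
    m = n_epochs if n_epochs is not None else n_samples // n
    finite = np.isfinite(roll_deg)
    vals = np.where(finite, roll_deg, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    centers = (np.arange(m) * n + n / 2.0).astype(int)
    lo = np.clip(centers - w // 2, 0, n_samples)
    hi = np.clip(centers + (w - w // 2), 0, n_samples)
    counts = ccnt[hi] - ccnt[lo]
    sums = csum[hi] - csum[lo]
    out = np.full(m, np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out


def classify_lmr(
    trace: AccelTrace,
    thresholds: Thresholds | None = None,
    filter_config: FilterConfig | None = None,
    posture_config: PostureConfig | None = None,
    epoch_length_s: float = 1.0,
    correct_rotation: bool = True,
) -> StateSeries:
    """Classify a trace into Active / RestHeadUp / RestHeadDown per epoch."""
    thresholds = thresholds or Thresholds()
    filter_config = filter_config or FilterConfig()
    posture_config = posture_config or PostureConfig()
    if trace.duration_s < posture_config.window_length_s:
        raise InsufficientDataError(
            f"trace of {trace.duration_s:.1f} s shorter than one "
            f"{posture_config.window_length_s:.0f} s posture window"
        )
    if correct_rotation:
        trace = CollarRotationCorrector(
            window_length_s=posture_config.window_length_s
        ).fit_transform(trace)

    low = ess_low_movement(
        lowpass_dv(trace, filter_config),
        trace.sampling_rate,
        delta_g=thresholds.delta_g,
        epoch_length_s=epoch_length_s,
    )
    orientation = pitch_roll(trace, posture_config)
    incline = centred_incline_means(
        orientation.roll_deg,
        trace.sampling_rate,
        epoch_length_s=epoch_length_s,
        window_length_s=posture_config.window_length_s,
        n_epochs=len(low.values),
    )
    head_up = incline >= thresholds.omega_deg  # NaN -> False -> HeadDown

    values = np.where(
        low.values == 0, ACTIVE, np.where(head_up, REST_HEAD_UP, REST_HEAD_DOWN)
    ).astype(object)
    return StateSeries(
        epoch_length_s=epoch_length_s, values=values, origin_s=trace.start_time
    )


class LMRClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator for the full LMR pipeline.

    ``predict`` maps traces to per-epoch :class:`~lmr.core.StateSeries`
    using the configured (or fitted) thresholds.  ``fit`` tunes ``delta_g``
    and ``omega_deg`` by the group equal-error (ROC crossing-point)
    criterion against annotated ground truth; the tuned values land in
    ``delta_g_`` / ``omega_deg_`` and are in-sample (no train/test split).
    """

    def __init__(
        self,
        delta_g: float = 0.014,
        omega_deg: float = 14.0,
        cutoff_hz: float = 3.0,
        filter_order: int = 1,
        mu: float = 0.1,
        epoch_length_s: float = 1.0,
        posture_window_s: float = 10.0,
        correct_rotation: bool = True,
        delta_grid: Optional[np.ndarray] = None,
        omega_grid: Optional[np.ndarray] = None,
    ):
        self.delta_g = delta_g
        self.omega_deg = omega_deg
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.mu = mu
        self.epoch_length_s = epoch_length_s
        self.posture_window_s = posture_window_s
        self.correct_rotation = correct_rotation
        self.delta_grid = delta_grid
        self.omega_grid = omega_grid

    # -- config plumbing ---------------------------------------------------

    def _filter_config(self) -> FilterConfig:
        return FilterConfig(cutoff_hz=self.cutoff_hz, order=self.filter_order)

    def _posture_config(self, omega: float) -> PostureConfig:
        return PostureConfig(
            mu=self.mu, window_length_s=self.posture_window_s, omega_deg=omega
        )

    def _thresholds(self) -> Thresholds:
        return Thresholds(
            delta_g=getattr(self, "delta_g_", self.delta_g),
            omega_deg=getattr(self, "omega_deg_", self.omega_deg),
        )

    # -- estimator API -----------------------------------------------------

    def fit(
        self,
        X: Sequence[AccelTrace],
        y: Sequence[AnnotationTrack | StateSeries],
    ) -> "LMRClassifier":
        from .threshold_optimizer import fit_thresholds

        fitted = fit_thresholds(
            list(X),
            list(y),
            delta_grid=self.delta_grid,
            omega_grid=self.omega_grid,
            filter_config=self._filter_config(),
            mu=self.mu,
            epoch_length_s=self.epoch_length_s,
            posture_window_s=self.posture_window_s,
            correct_rotation=self.correct_rotation,
        )
        self.delta_g_ = fitted.delta_g
        self.omega_deg_ = fitted.omega_deg
        self.roc_delta_ = fitted.delta_curves
        self.roc_omega_ = fitted.omega_curves
        self.classes_ = np.array([ACTIVE, REST_HEAD_DOWN, REST_HEAD_UP])
        return self

    def predict(
        self, X: AccelTrace | Sequence[AccelTrace]
    ) -> StateSeries | list[StateSeries]:
        thresholds = self._thresholds()

        def _one(trace: AccelTrace) -> StateSeries:
            return classify_lmr(
                trace,
                thresholds=thresholds,
                filter_config=self._filter_config(),
                posture_config=self._posture_config(thresholds.omega_deg),
                epoch_length_s=self.epoch_length_s,
                correct_rotation=self.correct_rotation,
            )

        if isinstance(X, AccelTrace):
            return _one(X)
        return [_one(trace) for trace in X]

    def score(
        self,
        X: AccelTrace | Sequence[AccelTrace],
        y: StateSeries | Sequence[StateSeries],
        sample_weight=None,
    ) -> float:
        """Mean per-epoch agreement with ground truth, Excluded skipped."""
        from .evaluation import epoch_accuracy

        if isinstance(X, AccelTrace):
            X, y = [X], [y]  # type: ignore[list-item]
        accs = [epoch_accuracy(pred, truth) for pred, truth in zip(self.predict(X), y)]
        return float(np.mean(accs))
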