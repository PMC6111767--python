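"""Shared containers, state alphabets and error types.

The package works in the subject's anatomical frame: after collar-rotation
correction the sensor x axis is anterior-posterior (AP, cranial-caudal),
y is medial-lateral (ML) and z is dorsal-ventral (DV).  Acceleration is in
units of standard gravity (g), so a stationary sensor reads a vector of
magnitude ~1 g whose orientation encodes posture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

# --- state alphabets ------------------------------------------------------

#: Per-epoch states emitted by the classifier / derived from annotations.
ACTIVE = "Active"
REST_HEAD_UP = "RestHeadUp"
REST_HEAD_DOWN = "RestHeadDown"
EXCLUDED = "Excluded"

STATE_LABELS = (ACTIVE, REST_HEAD_UP, REST_HEAD_DOWN, EXCLUDED)
REST_STATES = (REST_HEAD_UP, REST_HEAD_DOWN)

#: Closed annotation ethogram for the video ground truth.
REST = "Rest"
RESTING_HEAD_UP = "Resting-Head Up"
NOT_RESTING = "Not Resting"
OUT_OF_VIEW = "Out of View"

ETHOGRAM_LABELS = (REST, RESTING_HEAD_UP, NOT_RESTING, OUT_OF_VIEW)

#: Annotation label -> epoch state (Rest means recumbent head-down rest:
#: resting and *not* head-up; anything not resting is Alert/Active).
ETHOGRAM_TO_STATE = {
    REST: REST_HEAD_DOWN,
    RESTING_HEAD_UP: REST_HEAD_UP,
    NOT_RESTING: ACTIVE,
}

DEFAULT_AXIS_CONVENTION: Mapping[str, str] = {"x": "AP", "y": "ML", "z": "DV"}


# --- errors ---------------------------------------------------------------


class LMRError(Exception):
    """Base class for all package errors."""


class ConfigError(LMRError):
    """Invalid configuration value (bad threshold, cutoff >= Nyquist, ...)."""


class DataError(LMRError):
    """Input data violates a precondition."""


class FormatError(DataError):
    """A file does not follow the expected tabular layout."""


class SamplingError(DataError):
    """Timestamps are not uniformly sampled within tolerance."""


class LabelError(DataError):
    """An annotation label is outside the ethogram."""


class IntervalError(DataError):
    """An annotation interval is empty or inverted."""


class SyncError(DataError):
    """Clap synchronisation spikes could not be found."""


class AlignmentError(DataError):
    """Two epoch series do not share a grid."""


class InsufficientDataError(DataError):
    """Trace shorter than the minimum the operation needs."""


class DegenerateRocError(DataError):
    """Ground truth contains a single class; ROC undefined."""


# --- containers -----------------------------------------------------------


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, constant over the trace.
    ax, ay, az : ndarray
        Per-sample acceleration along AP, ML and DV respectively, in g.
    start_time : float
        Offset of the first sample in seconds.
    axis_convention : mapping
        Names the anatomical axis carried by each sensor axis.
    """

    sampling_rate: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    start_time: float = 0.0
    axis_convention: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_CONVENTION)
    )

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.ax)
        if n < 1 or len(self.ay) != n or len(self.az) != n:
            raise DataError("ax, ay, az must have equal length >= 1")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def magnitude(self) -> np.ndarray:
        """Per-sample vector magnitude |A| in g."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise IntervalError(
                f"interval [{self.start_s}, {self.end_s}] has non-positive length"
            )
        if self.label not in ETHOGRAM_LABELS:
            raise LabelError(f"label {self.label!r} not in ethogram {ETHOGRAM_LABELS}")


@dataclass
class AnnotationTrack:
    """Labelled behaviour intervals from the annotation ethogram.

    Intervals are kept sorted by start time.  Out of View may overlap the
    behavioural tiers; overlapping epochs are excluded from scoring.
    """

    intervals: list[Interval]

    def __post_init__(self) -> None:
        self.intervals = sorted(
            (iv if isinstance(iv, Interval) else Interval(*iv) for iv in self.intervals),
            key=lambda iv: (iv.start_s, iv.end_s),
        )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def span(self) -> tuple[float, float]:
        if not self.intervals:
            raise DataError("empty annotation track has no span")
        return (
            min(iv.start_s for iv in self.intervals),
            max(iv.end_s for iv in self.intervals),
        )


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous, half-open scoring epochs [t, t + epoch_length_s)."""

    epoch_length_s: float
    n_epochs: int
    origin_s: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ConfigError("epoch_length_s must be > 0")
        if self.n_epochs < 1:
            raise ConfigError("n_epochs must be >= 1")

    @property
    def starts(self) -> np.ndarray:
        return self.origin_s + self.epoch_length_s * np.arange(self.n_epochs)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + 0.5 * self.epoch_length_s

    @property
    def end_s(self) -> float:
        return self.origin_s + self.epoch_length_s * self.n_epochs


@dataclass
class StateSeries:
    """Per-epoch behavioural state on a fixed epoch grid."""

    epoch_length_s: float
    values: np.ndarray  # entries from STATE_LABELS
    origin_s: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ConfigError("epoch_length_s must be > 0")
        self.values = np.asarray(self.values, dtype=object)
        bad = set(self.values) - set(STATE_LABELS)
        if bad:
            raise LabelError(f"unknown state labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def grid(self) -> EpochGrid:
        return EpochGrid(self.epoch_length_s, len(self.values), self.origin_s)

    @property
    def starts(self) -> np.ndarray:
        return self.grid.starts

    def scored_mask(self) -> np.ndarray:
        """Boolean mask of epochs that are not Excluded."""
        return self.values != EXCLUDED


def check_same_grid(a: StateSeries | Sequence, b: StateSeries) -> None:
    """Raise :class:`AlignmentError` unless the two series share a grid."""
    if isinstance(a, StateSeries):
        if (
            a.epoch_length_s != b.epoch_length_s
            or len(a) != len(b)
            or a.origin_s != b.origin_s
        ):
            raise AlignmentError("state series are on different epoch grids")
    elif len(a) != len(b):
        raise AlignmentError("series lengths differ")
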