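"""ROC sweeps, per-subject crossing points and group best-fit thresholds.

Each decision threshold of the method is tuned by sweeping a grid,
recording sensitivity and specificity at every grid value against
annotated ground truth, and picking the equal-error ("crossing") point
where |SEN - SPC| is smallest.  The group threshold minimises the mean
|SEN - SPC| over subjects, tie-broken by maximal mean accuracy.  Fitting
is in-sample: no train/test partition is made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    EXCLUDED,
    REST_HEAD_DOWN,
    REST_HEAD_UP,
    REST_STATES,
    AccelTrace,
    AnnotationTrack,
    AlignmentError,
    DataError,
    DegenerateRocError,
    EpochGrid,
    StateSeries,
)
from .ess_detector import FilterConfig, epoch_sd, lowpass_dv
from .io_formats import annotations_to_epochs
from .posture import PostureConfig, head_incline_windows, pitch_roll
from .rotation import CollarRotationCorrector

DEFAULT_DELTA_GRID = np.round(np.arange(0.001, 0.1001, 0.001), 6)
DEFAULT_OMEGA_GRID = np.arange(1.0, 46.0, 1.0)


@dataclass
class RocCurve:
    """Sensitivity/specificity per grid threshold for one subject."""

    thresholds: np.ndarray
    sen: np.ndarray
    spc: np.ndarray
    acc: np.ndarray
    parameter_name: str = ""
    rule: str = "le"  # positive when statistic <= threshold ("ge": >=)

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.sen, self.spc))


def _binary_truth(truth: Sequence, positive_state) -> tuple[np.ndarray, np.ndarray]:
    pos = {positive_state} if isinstance(positive_state, str) else set(positive_state)
    values = truth.values if isinstance(truth, StateSeries) else np.asarray(truth, dtype=object)
    scored = values != EXCLUDED
    is_pos = np.array([v in pos for v in values])
    return is_pos, scored


def roc_sweep(
    per_epoch_statistic: np.ndarray,
    truth: StateSeries | Sequence,
    positive_state,
    grid: np.ndarray,
    rule: str = "le",
    parameter_name: str = "",
) -> RocCurve:
    """One (SEN, SPC) pair per grid threshold.

    ``rule`` gives the direction of the decision: "le" predicts positive
    when the statistic is <= the threshold (the low-movement delta sweep),
    "ge" when it is >= (the head-incline omega sweep).  Epochs that are
    Excluded or have a NaN statistic are skipped.  A single-class truth
    raises :class:`DegenerateRocError`.
    """
    stat = np.asarray(per_epoch_statistic, dtype=float)
    is_pos, scored = _binary_truth(truth, positive_state)
    if len(stat) != len(is_pos):
        raise AlignmentError("statistic and truth lengths differ")
    scored = scored & np.isfinite(stat)
    n_pos = int(np.sum(is_pos & scored))
    n_neg = int(np.sum(~is_pos & scored))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateRocError("ground truth has a single class; ROC undefined")
    if rule not in ("le", "ge"):
        raise DataError(f"unknown rule {rule!r}")
    grid = np.asarray(grid, dtype=float)
    sen = np.empty(len(grid))
    spc = np.empty(len(grid))
    acc = np.empty(len(grid))
    s, p = stat[scored], is_pos[scored]
    for i, thr in enumerate(grid):
        pred = s <= thr if rule == "le" else s >= thr
        tp = np.sum(pred & p)
        tn = np.sum(~pred & ~p)
        sen[i] = tp / n_pos
        spc[i] = tn / n_neg
        acc[i] = (tp + tn) / (n_pos + n_neg)
    return RocCurve(
        thresholds=grid, sen=sen, spc=spc, acc=acc,
        parameter_name=parameter_name, rule=rule,
    )


def _qualifying(objective: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    return np.flatnonzero(objective <= objective.min() + tol)


def crossing_point(curve: RocCurve) -> float:
    """Grid threshold minimising |SEN - SPC|.

    Ties break by maximal SEN + SPC, then by the median qualifying
    threshold.
    """
    diff = np.abs(curve.sen - curve.spc)
    idx = _qualifying(diff)
    total = curve.sen[idx] + curve.spc[idx]
    idx = idx[total >= total.max() - 1e-12]
    return float(curve.thresholds[idx[(len(idx) - 1) // 2]])


def group_best_fit(
    per_subject: Sequence[tuple[np.ndarray, StateSeries | Sequence]],
    grid: np.ndarray,
    positive_state,
    rule: str = "le",
    parameter_name: str = "",
) -> tuple[float, list[RocCurve]]:
    """Single threshold minimising the mean |SEN - SPC| over subjects.

    Ties break by maximal mean accuracy, then by the median qualifying
    threshold.  Subjects with degenerate (single-class) truth are excluded
    with a warning; at least one usable subject is required.
    """
    curves = []
    for i, (stat, truth) in enumerate(per_subject):
        try:
            curves.append(
                roc_sweep(stat, truth, positive_state, grid, rule, parameter_name)
            )
        except DegenerateRocError:
            warnings.warn(f"subject {i} excluded from group fit (single-class truth)")
    if not curves:
        raise DataError("no subject has both classes; cannot fit a group threshold")
    mean_diff = np.mean([np.abs(c.sen - c.spc) for c in curves], axis=0)
    mean_acc = np.mean([c.acc for c in curves], axis=0)
    idx = _qualifying(mean_diff)
    idx = idx[mean_acc[idx] >= mean_acc[idx].max() - 1e-12]
    grid = np.asarray(grid, dtype=float)
    return float(grid[idx[(len(idx) - 1) // 2]]), curves


# --- end-to-end fitting against annotations -------------------------------


@dataclass
class FittedThresholds:
    delta_g: float
    omega_deg: float
    delta_curves: list[RocCurve] = field(default_factory=list)
    omega_curves: list[RocCurve] = field(default_factory=list)


def _truth_series(
    truth: AnnotationTrack | StateSeries, epoch_length_s: float, n_epochs: int
) -> StateSeries:
    if isinstance(truth, StateSeries):
        return truth
    grid = EpochGrid(epoch_length_s=epoch_length_s, n_epochs=n_epochs, origin_s=0.0)
    return annotations_to_epochs(truth, grid)


def subject_statistics(
    trace: AccelTrace,
    truth: AnnotationTrack | StateSeries,
    filter_config: FilterConfig | None = None,
    mu: float = 0.1,
    epoch_length_s: float = 1.0,
    posture_window_s: float = 10.0,
    correct_rotation: bool = True,
):
    """Per-subject sweep statistics and aligned truth.

    Returns ``(sd_stat, sd_truth, incline_stat, incline_truth)``:

    * the 1 s-epoch SD of the filtered DV channel, with truth on the same
      grid (positive class for the delta sweep: either rest state);
    * the 10 s-window mean head-incline, with truth on the window grid and
      non-rest windows masked Excluded so the omega sweep only sees
      recumbent epochs (positive class: RestHeadUp).
    """
    if correct_rotation:
        trace = CollarRotationCorrector(window_length_s=posture_window_s).fit_transform(trace)
    filtered = lowpass_dv(trace, filter_config or FilterConfig())
    sd_stat = epoch_sd(filtered, trace.sampling_rate, epoch_length_s)
    sd_truth = _truth_series(truth, epoch_length_s, len(sd_stat))

    orientation = pitch_roll(trace, PostureConfig(mu=mu, window_length_s=posture_window_s))
    incline_stat = head_incline_windows(orientation, trace.sampling_rate, posture_window_s)
    incline_truth = _truth_series(truth, posture_window_s, len(incline_stat))
    masked = incline_truth.values.copy()
    masked[~np.isin(masked.astype(str), [REST_HEAD_UP, REST_HEAD_DOWN])] = EXCLUDED
    incline_truth = StateSeries(
        epoch_length_s=incline_truth.epoch_length_s,
        values=masked,
        origin_s=incline_truth.origin_s,
    )
    n = min(len(sd_stat), len(sd_truth))
    sd_stat = sd_stat[:n]
    sd_truth = StateSeries(epoch_length_s, sd_truth.values[:n], sd_truth.origin_s)
    m = min(len(incline_stat), len(incline_truth))
    incline_stat = incline_stat[:m]
    incline_truth = StateSeries(posture_window_s, incline_truth.values[:m], incline_truth.origin_s)
    return sd_stat, sd_truth, incline_stat, incline_truth


def fit_thresholds(
    traces: Sequence[AccelTrace],
    truths: Sequence[AnnotationTrack | StateSeries],
    delta_grid: Optional[np.ndarray] = None,
    omega_grid: Optional[np.ndarray] = None,
    filter_config: FilterConfig | None = None,
    mu: float = 0.1,
    epoch_length_s: float = 1.0,
    posture_window_s: float = 10.0,
    correct_rotation: bool = True,
) -> FittedThresholds:
    """Group best-fit delta (low-movement SD) and omega (head-incline)."""
    if len(traces) != len(truths) or not traces:
        raise DataError("need one ground truth per trace, at least one subject")
    delta_grid = DEFAULT_DELTA_GRID if delta_grid is None else np.asarray(delta_grid)
    omega_grid = DEFAULT_OMEGA_GRID if omega_grid is None else np.asarray(omega_grid)
    delta_subjects, omega_subjects = [], []
    for trace, truth in zip(traces, truths):
        sd_stat, sd_truth, inc_stat, inc_truth = subject_statistics(
            trace, truth, filter_config, mu, epoch_length_s,
            posture_window_s, correct_rotation,
        )
        delta_subjects.append((sd_stat, sd_truth))
        omega_subjects.append((inc_stat, inc_truth))
    delta, delta_curves = group_best_fit(
        delta_subjects, delta_grid, REST_STATES, rule="le", parameter_name="delta_g"
    )
    omega, omega_curves = group_best_fit(
        omega_subjects, omega_grid, REST_HEAD_UP, rule="ge", parameter_name="omega_deg"
    )
    return FittedThresholds(
        delta_g=delta, omega_deg=omega,
        delta_curves=delta_curves, omega_curves=omega_curves,
    )
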