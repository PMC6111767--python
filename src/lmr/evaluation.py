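"""Epoch-level scoring: confusion counts, PPV/NPV/SPC/SEN/ACC, group
summaries, and epoch-grid Cohen's kappa.

Epochs marked Excluded in either series never enter a count.  Metrics with
a zero denominator are reported as NaN (not-available), never silently 0.
Group summaries use the sample (n-1) standard deviation and are rounded to
two decimals for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .core import DataError, StateSeries, check_same_grid


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """PPV, NPV, specificity, sensitivity and accuracy for one subject."""

    ppv: float
    npv: float
    spc: float
    sen: float
    acc: float
    subject_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"ppv": self.ppv, "npv": self.npv, "spc": self.spc,
                "sen": self.sen, "acc": self.acc}


@dataclass
class GroupSummary:
    metric_name: str
    mean: float
    sd: float
    n_subjects: int


def _positive_set(positive_state) -> set:
    if isinstance(positive_state, str):
        return {positive_state}
    return set(positive_state)


def confusion(
    pred: StateSeries, truth: StateSeries, positive_state
) -> ConfusionCounts:
    """Count TP/FP/TN/FN with the given positive state (label or set).

    TP: both series positive.  FP: prediction positive, truth not.  TN:
    both negative.  FN: prediction negative, truth positive.
    """
    check_same_grid(pred, truth)
    pos = _positive_set(positive_state)
    scored = pred.scored_mask() & truth.scored_mask()
    p = np.array([v in pos for v in pred.values])
    t = np.array([v in pos for v in truth.values])
    return ConfusionCounts(
        tp=int(np.sum(scored & p & t)),
        fp=int(np.sum(scored & p & ~t)),
        tn=int(np.sum(scored & ~p & ~t)),
        fn=int(np.sum(scored & ~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts, subject_id: str = "") -> MetricsReport:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN), SPC = TN/(TN+FP),
    SEN = TP/(TP+FN), ACC = (TP+TN)/total."""
    c = counts
    return MetricsReport(
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        spc=_ratio(c.tn, c.tn + c.fp),
        sen=_ratio(c.tp, c.tp + c.fn),
        acc=_ratio(c.tp + c.tn, c.total),
        subject_id=subject_id,
    )


def epoch_accuracy(
    pred: StateSeries, truth: StateSeries, mask: Optional[np.ndarray] = None
) -> float:
    """Fraction of scored epochs whose states agree exactly (multi-class)."""
    check_same_grid(pred, truth)
    scored = pred.scored_mask() & truth.scored_mask()
    if mask is not None:
        scored &= mask
    if not scored.any():
        return float("nan")
    return float(np.mean(pred.values[scored] == truth.values[scored]))


def transition_mask(truth: StateSeries, n_epochs: int = 1) -> np.ndarray:
    """Mask that is False within ``n_epochs`` of a ground-truth state change.

    Useful for scoring steady-state behaviour: the epoch containing a
    behavioural transition is ambiguous on any epoch grid.
    """
    vals = truth.values
    keep = np.ones(len(vals), dtype=bool)
    change = np.flatnonzero(vals[1:] != vals[:-1]) + 1  # first epoch of new run
    for c in change:
        keep[max(0, c - n_epochs) : min(len(vals), c + n_epochs)] = False
    return keep


def aggregate_subjects(
    reports: Sequence[MetricsReport] | Iterable[float], metric_name: str
) -> GroupSummary:
    """Mean and sample SD of one metric across subjects, 2-dp rounded.

    Accepts either MetricsReport objects or raw per-subject values.
    Subjects whose metric is not-available are excluded with a warning.
    """
    values = []
    for r in reports:
        v = getattr(r, metric_name) if isinstance(r, MetricsReport) else float(r)
        if np.isnan(v):
            warnings.warn(
                f"subject {getattr(r, 'subject_id', '?')} excluded from "
                f"{metric_name} summary (metric not available)"
            )
            continue
        values.append(v)
    if len(values) < 2:
        raise DataError("need >= 2 subjects with a defined metric for a group summary")
    arr = np.asarray(values)
    return GroupSummary(
        metric_name=metric_name,
        mean=round(float(np.mean(arr)), 2),
        sd=round(float(np.std(arr, ddof=1)), 2),
        n_subjects=len(values),
    )


def cohens_kappa(truth_a: StateSeries, truth_b: StateSeries) -> float:
    """Chance-corrected agreement between two raters on the epoch grid.

    kappa = (p_o - p_e) / (1 - p_e).  When both raters are constant and
    identical (p_e = 1) kappa is defined as 1.
    """
    check_same_grid(truth_a, truth_b)
    scored = truth_a.scored_mask() & truth_b.scored_mask()
    if not scored.any():
        raise DataError("no jointly scored epochs")
    a = truth_a.values[scored].astype(str)
    b = truth_b.values[scored].astype(str)
    if len(set(a) | set(b)) == 1:
        return 1.0
    return float(cohen_kappa_score(a, b))
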