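"""Reading/writing traces and annotations; clap sync; epoch projection.

Accelerometer CSV layout: ``time_s, ax_g, ay_g, az_g`` with a header row.
Annotation layouts: generic CSV ``start_s, end_s, label`` and the ELAN
tab-delimited export dialect (tab-separated begin/end seconds plus an
annotation value, with optional leading tier columns).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    ACTIVE,
    DEFAULT_AXIS_CONVENTION,
    ETHOGRAM_LABELS,
    ETHOGRAM_TO_STATE,
    EXCLUDED,
    OUT_OF_VIEW,
    AccelTrace,
    AnnotationTrack,
    DataError,
    EpochGrid,
    FormatError,
    Interval,
    LabelError,
    SamplingError,
    StateSeries,
    SyncError,
)

ACCEL_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")

#: Accepted spellings of the ethogram labels (lower-case key).
_LABEL_ALIASES = {
    "rest": "Rest",
    "resting": "Rest",
    "rest-head up": "Resting-Head Up",
    "rest head up": "Resting-Head Up",
    "resting-head up": "Resting-Head Up",
    "resting head up": "Resting-Head Up",
    "not resting": "Not Resting",
    "notresting": "Not Resting",
    "out of view": "Out of View",
    "oov": "Out of View",
}


def normalise_label(label: str) -> str:
    """Map a raw annotation label onto the closed ethogram set."""
    key = str(label).strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise LabelError(f"unknown annotation label {label!r}; expected one of {ETHOGRAM_LABELS}")


# --- accelerometer CSV ----------------------------------------------------


def read_accel_csv(
    path: str | Path,
    axis_convention: Mapping[str, str] | None = None,
    jitter_tol: float = 0.01,
) -> AccelTrace:
    """Read a trace CSV, inferring the sampling rate from the time column.

    The time column must be strictly increasing and uniformly spaced within
    ``jitter_tol`` (relative to the median step); otherwise a
    :class:`SamplingError` is raised.
    """
    df = pd.read_csv(path)
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples to infer sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > jitter_tol * step):
        raise SamplingError(
            f"{path}: non-uniform sampling (max deviation "
            f"{np.max(np.abs(dt - step)):.3g} s vs median step {step:.3g} s)"
        )
    return AccelTrace(
        sampling_rate=1.0 / step,
        ax=df["ax_g"].to_numpy(dtype=float),
        ay=df["ay_g"].to_numpy(dtype=float),
        az=df["az_g"].to_numpy(dtype=float),
        start_time=float(t[0]),
        axis_convention=dict(axis_convention or DEFAULT_AXIS_CONVENTION),
    )


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "ax_g": trace.ax,
            "ay_g": trace.ay,
            "az_g": trace.az,
        }
    ).to_csv(path, index=False, float_format="%.12g")


# --- annotations ----------------------------------------------------------


def read_annotations(path: str | Path, dialect: str = "generic-csv") -> AnnotationTrack:
    """Read behaviour intervals from ``generic-csv`` or ``elan-tab`` files."""
    if dialect == "generic-csv":
        rows = _read_generic_csv(path)
    elif dialect == "elan-tab":
        rows = _read_elan_tab(path)
    else:
        raise FormatError(f"unknown annotation dialect {dialect!r}")
    intervals = [
        Interval(start_s=s, end_s=e, label=normalise_label(lab)) for s, e, lab in rows
    ]
    if not intervals:
        raise FormatError(f"{path}: no annotation rows found")
    return AnnotationTrack(intervals)


def _read_generic_csv(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    missing = [c for c in ("start_s", "end_s", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        (float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()
    ]


def _read_elan_tab(path: str | Path) -> list[tuple[float, float, str]]:
    """Parse an ELAN tab-delimited export.

    Exports vary in their leading tier/participant columns; rows are
    interpreted as: first two numeric fields = begin/end seconds (a third
    consecutive numeric field, the duration, is ignored), last field = label.
    """
    rows: list[tuple[float, float, str]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            numeric = []
            for f in fields:
                try:
                    numeric.append(float(f))
                except ValueError:
                    continue
            if len(numeric) < 2:
                raise FormatError(f"{path}:{lineno}: no begin/end times found")
            rows.append((numeric[0], numeric[1], fields[-1].strip()))
    return rows


def write_annotations_csv(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for iv in track.intervals:
            w.writerow([f"{iv.start_s:.6f}", f"{iv.end_s:.6f}", iv.label])


# --- state series CSV -----------------------------------------------------


def write_states_csv(states: StateSeries, path: str | Path) -> None:
    pd.DataFrame({"epoch_start_s": states.starts, "state": states.values}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_states_csv(path: str | Path) -> StateSeries:
    df = pd.read_csv(path)
    missing = [c for c in ("epoch_start_s", "state") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    if len(starts) < 2:
        raise FormatError(f"{path}: need at least two epochs")
    step = float(np.median(np.diff(starts)))
    return StateSeries(
        epoch_length_s=step,
        values=df["state"].to_numpy(dtype=object),
        origin_s=float(starts[0]),
    )


# --- clap synchronisation -------------------------------------------------


def detect_clap_sync(
    trace: AccelTrace,
    n_claps: int = 5,
    magnitude_threshold: float = 2.0,
    min_gap_s: float = 0.2,
) -> np.ndarray:
    """Locate the first ``n_claps`` vector-magnitude spikes above threshold.

    Claps are sharp, high-g transients recorded while the instrumented
    collar is held in front of the camera; their timestamps give the
    video-to-sensor offset.  Raises :class:`SyncError` when fewer than
    ``n_claps`` qualifying peaks exist.
    """
    if n_claps < 1:
        raise DataError("n_claps must be >= 1")
    mag = trace.magnitude()
    distance = max(1, int(round(min_gap_s * trace.sampling_rate)))
    peaks, _ = find_peaks(mag, height=magnitude_threshold, distance=distance)
    if len(peaks) < n_claps:
        raise SyncError(
            f"found {len(peaks)} peaks above {magnitude_threshold} g, need {n_claps}"
        )
    return trace.start_time + peaks[:n_claps] / trace.sampling_rate


# --- epoch projection -----------------------------------------------------


def annotations_to_epochs(track: AnnotationTrack, grid: EpochGrid) -> StateSeries:
    """Project annotation intervals onto an epoch grid as ground-truth states.

    Each epoch takes the majority-duration behavioural label within it,
    mapped to the state alphabet (Rest -> RestHeadDown, Resting-Head Up ->
    RestHeadUp, Not Resting -> Active).  Ties break toward Active.  Any
    overlap with an Out of View interval, or an epoch with no annotation
    cover at all, marks the epoch Excluded.
    """
    if len(track) == 0:
        raise DataError("empty annotation track")
    labels = [lab for lab in ETHOGRAM_LABELS if lab != OUT_OF_VIEW]
    cover = np.zeros((grid.n_epochs, len(labels)))
    oov = np.zeros(grid.n_epochs, dtype=bool)
    starts = grid.starts
    dt = grid.epoch_length_s
    for iv in track.intervals:
        lo = int(np.floor((iv.start_s - grid.origin_s) / dt))
        hi = int(np.ceil((iv.end_s - grid.origin_s) / dt))
        lo = max(lo, 0)
        hi = min(hi, grid.n_epochs)
        if hi <= lo:
            continue
        e_starts = starts[lo:hi]
        overlap = np.minimum(iv.end_s, e_starts + dt) - np.maximum(iv.start_s, e_starts)
        overlap = np.clip(overlap, 0.0, None)
        if iv.label == OUT_OF_VIEW:
            oov[lo:hi] |= overlap > 0
        else:
            cover[lo:hi, labels.index(iv.label)] += overlap

    values = np.empty(grid.n_epochs, dtype=object)
    best = np.argmax(cover, axis=1)  # first (i.e. ethogram order) argmax
    total = cover.sum(axis=1)
    for i in range(grid.n_epochs):
        if oov[i] or total[i] <= 0:
            values[i] = EXCLUDED
            continue
        # majority label; exact ties go to Not Resting (conservative: Active)
        top = cover[i].max()
        winners = [labels[j] for j in range(len(labels)) if cover[i, j] == top]
        if len(winners) > 1 and "Not Resting" in winners:
            values[i] = ACTIVE
        else:
            values[i] = ETHOGRAM_TO_STATE[labels[best[i]]]
    return StateSeries(epoch_length_s=dt, values=values, origin_s=grid.origin_s)


def grid_covering(track: AnnotationTrack, epoch_length_s: float) -> EpochGrid:
    """Smallest grid starting at the track's first instant covering its span."""
    lo, hi = track.span
    n = max(1, int(np.floor((hi - lo) / epoch_length_s)))
    return EpochGrid(epoch_length_s=epoch_length_s, n_epochs=n, origin_s=lo)
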