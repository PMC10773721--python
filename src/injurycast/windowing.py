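"""Sliding-window construction and per-athlete normalization of training logs.

A *day-approach* sample is the matrix of the 7 days of training-load
variables preceding a prediction day, labelled by whether an injury occurred
on that prediction day.  Windows are padded from 7 to 8 time steps so that
two pooling/upsampling stages of the convolutional auto-encoder round-trip
the spatial size (8 -> 4 -> 2 -> 4 -> 8).

All loads are min-max normalized *within each athlete* so that models compare
relative load patterns across athletes rather than absolute volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Number of daily training-load variables.
N_VARIABLES = 10
#: Days of history per window (before padding).
WINDOW_DAYS = 7
#: Time steps per window after padding.
PADDED_DAYS = 8

#: Default variable names, in column order.  The CSV reader binds columns by
#: position; these names are configurable metadata, not a contract.
DEFAULT_VARIABLE_NAMES: tuple[str, ...] = (
    "nr_sessions",
    "total_km",
    "km_Z3_4",
    "km_Z5_T1_T2",
    "km_sprinting",
    "strength_training",
    "hours_alternative",
    "perceived_exertion",
    "perceived_trainingSuccess",
    "perceived_recovery",
)

#: Indices of the variables that are bounded perceived ratings (0-10 scale).
RATING_VARIABLES: tuple[int, ...] = (7, 8, 9)


@dataclass
class TrainingDayRecord:
    """One athlete-day of training loads.

    ``injured_next_day`` flags an injury event on the day *after*
    ``day_index``; it becomes the label of the window whose last history day
    is this record.  ``risk_score`` carries the generator's latent linear
    predictor for synthetic cohorts (``nan`` for real data); it is never
    written to CSV and never visible to models.
    """

    athlete_id: str
    day_index: int
    loads: np.ndarray  # shape (10,)
    injured_next_day: int = 0
    risk_score: float = float("nan")

    def __post_init__(self) -> None:
        self.loads = np.asarray(self.loads, dtype=float)
        if self.loads.shape != (N_VARIABLES,):
            raise ValueError(
                f"loads must have exactly {N_VARIABLES} entries, "
                f"got shape {self.loads.shape}"
            )


@dataclass
class WindowSample:
    """A 7x10 (or, after padding, 8x10) window with its injury label.

    ``day_index`` is the prediction day: the day following the last history
    row.  Rows are ordered oldest first.
    """

    athlete_id: str
    day_index: int
    matrix: np.ndarray
    label: int
    risk_score: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_VARIABLES:
            raise ValueError(f"window matrix must be (7|8, {N_VARIABLES}), got {self.matrix.shape}")


@dataclass
class NormalizationState:
    """Per (athlete, variable) min/max used by the affine map x -> (x-min)/(max-min).

    Variables that are constant within an athlete map to 0 by convention.
    """

    minima: dict[str, np.ndarray] = field(default_factory=dict)
    maxima: dict[str, np.ndarray] = field(default_factory=dict)

    def transform_matrix(self, athlete_id: str, matrix: np.ndarray) -> np.ndarray:
        if athlete_id not in self.minima:
            raise KeyError(f"no normalization state for athlete {athlete_id!r}")
        lo = self.minima[athlete_id]
        hi = self.maxima[athlete_id]
        span = hi - lo
        out = np.zeros_like(np.asarray(matrix, dtype=float))
        ok = span > 0
        out[:, ok] = (matrix[:, ok] - lo[ok]) / span[ok]
        return out


def normalize_per_athlete(
    records: Sequence[TrainingDayRecord],
) -> tuple[list[TrainingDayRecord], NormalizationState]:
    """Min-max normalize each variable within each athlete's full history.

    Returns normalized copies of the records plus the fitted state, which can
    be re-applied to later data from the same athletes.  Constant variables
    (max == min) map to 0.
    """
    if not records:
        raise ValueError("no records to normalize")
    state = NormalizationState()
    by_athlete: dict[str, list[TrainingDayRecord]] = {}
    for rec in records:
        by_athlete.setdefault(rec.athlete_id, []).append(rec)
    out: list[TrainingDayRecord] = []
    for aid, recs in by_athlete.items():
        values = np.stack([r.loads for r in recs])
        state.minima[aid] = values.min(axis=0)
        state.maxima[aid] = values.max(axis=0)
        norm = state.transform_matrix(aid, values)
        for r, row in zip(recs, norm):
            out.append(replace(r, loads=row))
    return out, state


def normalize_windows(
    windows: Sequence[WindowSample],
) -> tuple[list[WindowSample], NormalizationState]:
    """Per-athlete min-max normalization computed over window contents.

    Used when data arrive already windowed (the day-approach CSV layout):
    the min/max per variable are taken over every value appearing in that
    athlete's windows.
    """
    if not windows:
        raise ValueError("no windows to normalize")
    state = NormalizationState()
    by_athlete: dict[str, list[WindowSample]] = {}
    for w in windows:
        by_athlete.setdefault(w.athlete_id, []).append(w)
    out: list[WindowSample] = []
    for aid, ws in by_athlete.items():
        stacked = np.concatenate([w.matrix for w in ws], axis=0)
        state.minima[aid] = stacked.min(axis=0)
        state.maxima[aid] = stacked.max(axis=0)
        for w in ws:
            out.append(replace(w, matrix=state.transform_matrix(aid, w.matrix)))
    return out, state


def build_windows(records: Iterable[TrainingDayRecord]) -> list[WindowSample]:
    """Assemble day-approach windows from day-level records.

    One window per prediction day: the 7 consecutive days before a day that
    is itself observed.  Windows never cross athletes; any gap in the day
    index invalidates the windows that would span it (skipped and logged).
    A contiguous block of ``d`` days yields ``d - 7`` windows.
    """
    by_athlete: dict[str, list[TrainingDayRecord]] = {}
    for rec in records:
        by_athlete.setdefault(rec.athlete_id, []).append(rec)
    windows: list[WindowSample] = []
    n_skipped = 0
    for aid, recs in by_athlete.items():
        recs = sorted(recs, key=lambda r: r.day_index)
        index = {r.day_index: r for r in recs}
        for rec in recs:
            start = rec.day_index  # first history day
            history = [index.get(start + k) for k in range(WINDOW_DAYS)]
            pred_day = start + WINDOW_DAYS
            if any(h is None for h in history) or pred_day not in index:
                if rec.day_index + WINDOW_DAYS <= recs[-1].day_index:
                    n_skipped += 1
                continue
            last = history[-1]
            windows.append(
                WindowSample(
                    athlete_id=aid,
                    day_index=pred_day,
                    matrix=np.stack([h.loads for h in history]),
                    label=int(last.injured_next_day),
                    risk_score=last.risk_score,
                )
            )
    if n_skipped:
        logger.info("build_windows: skipped %d windows with day-index gaps", n_skipped)
    return windows


def pad_window(matrix: np.ndarray, mode: str = "edge") -> np.ndarray:
    """Pad a 7x10 window to 8x10 by appending one time step.

    ``mode='edge'`` (default) replicates the last observed day, adding no
    spurious discontinuity to the angular/recurrence encodings; ``mode='zero'``
    appends a zero row.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (WINDOW_DAYS, N_VARIABLES):
        raise ValueError(f"pad_window expects shape (7, {N_VARIABLES}), got {matrix.shape}")
    if mode == "edge":
        pad_row = matrix[-1:]
    elif mode == "zero":
        pad_row = np.zeros((1, N_VARIABLES))
    else:
        raise ValueError(f"unknown padding mode {mode!r}; use 'edge' or 'zero'")
    return np.concatenate([matrix, pad_row], axis=0)


def pad_windows(windows: Sequence[WindowSample], mode: str = "edge") -> list[WindowSample]:
    """Pad every window in a collection (see :func:`pad_window`)."""
    return [replace(w, matrix=pad_window(w.matrix, mode=mode)) for w in windows]


def windows_to_arrays(
    windows: Sequence[WindowSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack a window collection into (matrices, labels, athlete_ids, day_indices)."""
    X = np.stack([w.matrix for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    aids = np.array([w.athlete_id for w in windows])
    days = np.array([w.day_index for w in windows], dtype=int)
    return X, y, aids, days


def save_windows(path, windows: Sequence[WindowSample]) -> None:
    """Serialize windows to an NPZ archive (matrices, labels, ids, days)."""
    X, y, aids, days = windows_to_arrays(windows)
    risk = np.array([w.risk_score for w in windows], dtype=float)
    np.savez(path, matrices=X, labels=y, athlete_ids=aids, day_indices=days, risk=risk)


def load_windows(path) -> list[WindowSample]:
    """Inverse of :func:`save_windows`."""
    with np.load(path, allow_pickle=False) as archive:
        X = archive["matrices"]
        y = archive["labels"]
        aids = archive["athlete_ids"]
        days = archive["day_indices"]
        risk = archive["risk"]
    return [
        WindowSample(str(a), int(d), m, int(label), float(r))
        for a, d, m, label, r in zip(aids, days, X, y, risk)
    ]
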