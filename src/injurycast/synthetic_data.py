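"""Synthetic athlete training-log generator and day-approach CSV I/O.

Emulates the structure of a multi-year training log of a competitive running
team: ~74 athletes, 10 daily load variables (session count, kilometres in
intensity zones, sprinting, strength and alternative training, and three
perceived 0-10 ratings), rare next-day injury events (~1.3% of windows), and
athlete-specific load scales.

Injuries are planted through a logistic model on two within-athlete
standardized quantities: the 7-day cumulative training volume (total km +
alternative-training hours) and the acute day-over-day jump in volume.  The
signal lives in *relative* load because the downstream pipeline min-max
normalizes each athlete separately, so absolute volumes carry no usable
information; this mirrors acute:chronic workload reasoning in sports science.
The model intercept is calibrated by bisection so the realized prevalence
matches the requested target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windowing import (
    DEFAULT_VARIABLE_NAMES,
    N_VARIABLES,
    WINDOW_DAYS,
    TrainingDayRecord,
    WindowSample,
    build_windows,
)

logger = logging.getLogger(__name__)

#: Default planted risk coefficients: (7-day cumulative volume, acute jump),
#: both on within-athlete z-scales.
DEFAULT_RISK_COEFFICIENTS = (1.0, 1.5)

#: Index of total_km and hours_alternative in the variable vector.
_KM_IDX = 1
_ALT_IDX = 6


class CalibrationError(RuntimeError):
    """Raised when the injury-rate calibration cannot reach the target."""


@dataclass
class AthleteProfile:
    """Per-athlete generative parameters."""

    athlete_id: str
    base_load: np.ndarray  # per-variable mean daily value on a training day
    load_sd: np.ndarray  # day-to-day spread
    rest_probability: float
    injury_susceptibility: float  # multiplicative frailty, > 0

    def __post_init__(self) -> None:
        self.base_load = np.asarray(self.base_load, dtype=float)
        self.load_sd = np.asarray(self.load_sd, dtype=float)
        if (self.base_load < 0).any():
            raise ValueError("base_load values must be non-negative")
        if self.injury_susceptibility < 0:
            raise ValueError("injury_susceptibility must be >= 0")


def _draw_profiles(n_athletes: int, rng: np.random.Generator,
                   susceptibility_sd: float) -> list[AthleteProfile]:
    profiles = []
    for i in range(n_athletes):
        base_km = rng.uniform(6.0, 14.0)
        base = np.zeros(N_VARIABLES)
        base[0] = 1.0 + rng.uniform(0.0, 0.5)          # sessions
        base[_KM_IDX] = base_km                        # total km
        base[2] = base_km * rng.uniform(0.10, 0.25)    # km Z3-4
        base[3] = base_km * rng.uniform(0.03, 0.10)    # km Z5-T1-T2
        base[4] = base_km * rng.uniform(0.005, 0.02)   # km sprinting
        base[5] = rng.uniform(0.2, 0.5)                # strength training (h)
        base[_ALT_IDX] = rng.uniform(0.2, 0.8)         # alternative training (h)
        base[7] = rng.uniform(4.5, 6.5)                # perceived exertion
        base[8] = rng.uniform(5.5, 7.5)                # perceived training success
        base[9] = rng.uniform(5.0, 7.0)                # perceived recovery
        sd = 0.35 * base
        sd[7:] = 1.2                                   # rating noise on the 0-10 scale
        profiles.append(
            AthleteProfile(
                athlete_id=f"athlete_{i:03d}",
                base_load=base,
                load_sd=sd,
                rest_probability=rng.uniform(0.20, 0.35),
                injury_susceptibility=float(np.exp(rng.normal(0.0, susceptibility_sd))),
            )
        )
    return profiles


def _simulate_loads(profile: AthleteProfile, n_days: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Daily 10-vector loads for one athlete; zero km on rest days."""
    loads = np.zeros((n_days, N_VARIABLES))
    rest = rng.uniform(size=n_days) < profile.rest_probability
    noise = rng.normal(size=(n_days, N_VARIABLES))
    values = profile.base_load + noise * profile.load_sd
    values = np.clip(values, 0.0, None)
    # occasional heavy-load blocks: multiply km variables by a slow AR drift
    drift = np.ones(n_days)
    for t in range(1, n_days):
        drift[t] = np.clip(0.9 * drift[t - 1] + 0.1 + rng.normal(0.0, 0.08), 0.5, 1.8)
    values[:, 1:5] *= drift[:, None]
    loads[:] = values
    loads[rest, 0:7] = 0.0  # no sessions, km, strength or alternative work
    loads[:, 0] = np.round(loads[:, 0])
    # exertion tracks the day's km on the athlete's own scale
    km = loads[:, _KM_IDX]
    km_sd = km.std() or 1.0
    loads[:, 7] += 1.2 * (km - km.mean()) / km_sd
    loads[:, 7:] = np.clip(loads[:, 7:], 0.0, 10.0)
    loads[rest, 7] = np.clip(rng.uniform(0.0, 2.0, size=int(rest.sum())), 0.0, 10.0)
    return loads


def _window_risk_terms(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each day t >= 6: 7-day cumulative volume and acute jump, plus valid mask."""
    n = len(volume)
    valid = np.zeros(n, dtype=bool)
    cum = np.full(n, np.nan)
    jump = np.full(n, np.nan)
    for t in range(WINDOW_DAYS - 1, n):
        window = volume[t - 6 : t + 1]
        cum[t] = window.sum()
        jump[t] = volume[t] - window[:-1].mean()
        valid[t] = True
    return cum, jump, valid


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def generate_cohort(
    n_athletes: int = 74,
    n_days: int = 400,
    prevalence_target: float = 0.013,
    risk_coefficients=DEFAULT_RISK_COEFFICIENTS,
    seed: int = 0,
    susceptibility_sd: float = 0.25,
    intercept: float | None = None,
    calibration_slack: float = 3.0,
) -> list[TrainingDayRecord]:
    """Generate a cohort of day-level training records with planted injury risk.

    The injury indicator of day ``t`` (stored as ``injured_next_day`` on that
    day, labelling the window ending there) is Bernoulli with probability
    ``sigmoid(c + b_vol * z_cum + b_jump * z_jump + log(frailty))`` where the
    z-scores are within-athlete standardizations of 7-day cumulative volume
    and acute volume jump, and the intercept ``c`` is found by bisection so
    the expected prevalence equals ``prevalence_target``.  With all
    coefficients zero, injuries are i.i.d. at the base rate.

    Deterministic for a fixed seed.  Raises :class:`CalibrationError` if the
    realized event count misses the expected count by more than 30% plus
    ``calibration_slack`` binomial standard deviations (the latter term keeps
    small cohorts, whose realized rate is dominated by sampling noise, from
    failing spuriously; at reference scale the 30% band dominates).

    Passing ``intercept`` fixes the logistic intercept instead of calibrating
    it (and skips the prevalence check); useful for studying how the risk
    coefficients alone move the injury rate.
    """
    if n_athletes < 2:
        raise ValueError("n_athletes must be >= 2")
    if n_days < 14:
        raise ValueError("n_days must be >= 14")
    if not 0.0 < prevalence_target < 0.5:
        raise ValueError("prevalence_target must lie in (0, 0.5)")
    coeffs = np.asarray(risk_coefficients, dtype=float)
    if coeffs.shape != (2,):
        raise ValueError("risk_coefficients must be (volume, jump)")

    rng = np.random.default_rng(seed)
    profiles = _draw_profiles(n_athletes, rng, susceptibility_sd)
    all_loads = [_simulate_loads(p, n_days, rng) for p in profiles]

    # latent linear predictor, pre-intercept
    etas, valids = [], []
    for profile, loads in zip(profiles, all_loads):
        volume = loads[:, _KM_IDX] + loads[:, _ALT_IDX]
        cum, jump, valid = _window_risk_terms(volume)
        eta = coeffs[0] * _zscore(cum) + coeffs[1] * _zscore(jump)
        eta = np.where(valid, eta, np.nan) + np.log(profile.injury_susceptibility)
        etas.append(eta)
        valids.append(valid)
    flat_eta = np.concatenate([e[v] for e, v in zip(etas, valids)])

    def mean_prob(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + flat_eta)))))

    calibrated = intercept is None
    if calibrated:
        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mean_prob(mid) < prevalence_target:
                lo = mid
            else:
                hi = mid
        intercept = 0.5 * (lo + hi)

    records: list[TrainingDayRecord] = []
    n_events = n_valid = 0
    for profile, loads, eta, valid in zip(profiles, all_loads, etas, valids):
        u = rng.uniform(size=n_days)
        for t in range(n_days):
            if valid[t]:
                score = intercept + eta[t]
                p = 1.0 / (1.0 + np.exp(-score))
                injured = int(u[t] < p)
                n_events += injured
                n_valid += 1
            else:
                score, injured = float("nan"), 0
            records.append(
                TrainingDayRecord(
                    athlete_id=profile.athlete_id,
                    day_index=t,
                    loads=loads[t],
                    injured_next_day=injured,
                    risk_score=score,
                )
            )
    realized = n_events / max(n_valid, 1)
    expected = n_valid * prevalence_target
    band = 0.3 * expected + calibration_slack * np.sqrt(
        n_valid * prevalence_target * (1.0 - prevalence_target))
    if calibrated and abs(n_events - expected) > band:
        raise CalibrationError(
            f"could not calibrate injury prevalence: target {prevalence_target:.4f}, "
            f"achieved {realized:.4f} over {n_valid} windows"
        )
    logger.info("generated cohort: %d athletes, %d days, prevalence %.4f",
                n_athletes, n_days, realized)
    return records


# ---------------------------------------------------------------------------
# Day-approach CSV layout
# ---------------------------------------------------------------------------

def _feature_columns(variable_names) -> list[str]:
    """70 feature columns, variable-major, oldest day first within each group.

    ``<var>_d7`` is 7 days before the prediction day, ``<var>_d1`` the day
    immediately before it (most recent last).
    """
    cols = []
    for var in variable_names:
        for back in range(WINDOW_DAYS, 0, -1):
            cols.append(f"{var}_d{back}")
    return cols


def write_day_approach_csv(records, path, variable_names=DEFAULT_VARIABLE_NAMES) -> int:
    """Window day-level records and write them as day-approach CSV rows.

    One row per prediction day: ``athlete_id, day_index, <70 features>,
    injury``.  Returns the number of rows written.  Requires at least one
    athlete with >= 8 consecutive days.
    """
    if len(variable_names) != N_VARIABLES:
        raise ValueError(f"need exactly {N_VARIABLES} variable names")
    windows = build_windows(records)
    if not windows:
        raise ValueError("no complete windows: every athlete needs >= 8 consecutive days")
    rows = []
    for w in windows:
        # matrix rows are oldest-first; flatten variable-major
        rows.append([w.athlete_id, w.day_index, *w.matrix.T.reshape(-1), w.label])
    frame = pd.DataFrame(rows, columns=["athlete_id", "day_index",
                                        *_feature_columns(variable_names), "injury"])
    # %.17g guarantees exact float round-trips through the text format
    frame.to_csv(path, index=False, float_format="%.17g")
    return len(rows)


class DayApproachParseError(ValueError):
    """Malformed day-approach CSV; message carries the offending row."""


def read_day_approach_csv(path, layout: str = "variable-major") -> list[WindowSample]:
    """Read a day-approach CSV into 7x10 window samples.

    Columns are bound by position: an athlete-id column, an optional
    day/date column, exactly 70 numeric feature columns, and a binary injury
    label.  ``layout`` states how the 70 columns are grouped:
    ``"variable-major"`` (this package's writer: 7 day-columns per variable,
    oldest first) or ``"day-major"`` (10 variable-columns per day, as in the
    public competitive-runners dataset).
    """
    if layout not in ("variable-major", "day-major"):
        raise ValueError(f"unknown layout {layout!r}")
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = list(frame.columns)
    lowered = [c.lower() for c in cols]
    athlete_col = next((c for c, l in zip(cols, lowered) if "athlete" in l), cols[0])
    label_col = next((c for c, l in zip(cols, lowered) if "injur" in l), None)
    if label_col is None:
        raise DayApproachParseError("no injury label column found")
    day_col = next((c for c, l in zip(cols, lowered) if l in ("day_index", "date", "day")), None)
    feature_cols = [c for c in cols if c not in (athlete_col, label_col, day_col)]
    if len(feature_cols) != WINDOW_DAYS * N_VARIABLES:
        raise DayApproachParseError(
            f"expected {WINDOW_DAYS * N_VARIABLES} feature columns, found {len(feature_cols)}"
        )
    features = frame[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = features.isna().any(axis=1)
    if bad.any():
        raise DayApproachParseError(f"non-numeric feature cell at row {int(np.flatnonzero(bad)[0])}")
    labels = pd.to_numeric(frame[label_col], errors="coerce")
    if labels.isna().any():
        raise DayApproachParseError(f"missing or non-numeric label at row {int(labels.isna().idxmax())}")

    values = features.to_numpy(dtype=float)
    windows: list[WindowSample] = []
    for i in range(len(frame)):
        if layout == "variable-major":
            matrix = values[i].reshape(N_VARIABLES, WINDOW_DAYS).T
        else:
            matrix = values[i].reshape(WINDOW_DAYS, N_VARIABLES)
        day = int(frame[day_col].iloc[i]) if day_col is not None else i
        windows.append(
            WindowSample(
                athlete_id=str(frame[athlete_col].iloc[i]),
                day_index=day,
                matrix=matrix,
                label=int(labels.iloc[i]),
            )
        )
    return windows
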