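"""Minimally invasive brood-rearing detection from comb-temperature telemetry.

Honey-bee brood needs a brood-nest temperature of roughly 32-37 degC held
within a 1-2 degC daily band, while the broodless winter cluster is cooler
and much more variable. The detector therefore reduces each colony-day to
the single warmest sensor and calls a brood day when that sensor's daily
maximum is >= 32 degC *and* its daily amplitude (max - min) is <= 2 degC.
Brood onset requires at least three consecutive brood days; a colony is
considered dead or too weak from the first day of a terminal run in which
the daily maximum stays at or below 17 degC without recovery.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectionThresholds",
    "daily_stats",
    "select_daily_max_sensor",
    "classify_brood_days",
    "detect_onset",
    "detect_death",
    "build_survival_records",
    "proportion_brood_days",
    "analyze_colony",
]

SAMPLES_PER_FULL_DAY = 8  # 3-hour grid, day boundary at 00:00


@dataclass(frozen=True)
class DetectionThresholds:
    """Rule thresholds; defaults are the published detection rules."""

    t_brood: float = 32.0  # daily max >= t_brood (inclusive)
    amp_max: float = 2.0  # daily amplitude <= amp_max (inclusive)
    min_run: int = 3  # consecutive brood days required for onset
    t_dead: float = 17.0  # daily max <= t_dead, unrecovered, marks death
    include_partial_days: bool = True


def daily_stats(samples: pd.DataFrame) -> pd.DataFrame:
    """Per colony x sensor x day max/min/mean of the 3-hourly samples.

    Days with fewer than the 8 samples of a complete day are kept but
    flagged ``partial``; days with no samples are absent. Duplicate
    (colony, sensor, timestamp) rows are an error.
    """
    df = samples.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.duplicated(["colony_id", "sensor_id", "timestamp"]).any():
        raise ValueError("duplicate (colony_id, sensor_id, timestamp) samples")
    df["date"] = df["timestamp"].dt.normalize()
    g = df.groupby(["colony_id", "sensor_id", "date"], sort=True)["temp_c"]
    out = g.agg(tmax="max", tmin="min", tmean="mean", n_samples="count").reset_index()
    out["partial"] = out["n_samples"] < SAMPLES_PER_FULL_DAY
    return out


def select_daily_max_sensor(stats: pd.DataFrame) -> pd.DataFrame:
    """Keep, per colony-day, the sensor with the highest daily maximum.

    Ties on the maximum are broken by list order, i.e. the lowest sensor
    id. The amplitude is the selected sensor's own max - min; selection is
    by maximum only, never by amplitude.
    """
    if stats.empty:
        raise ValueError("no daily stats to select from")
    df = stats.sort_values(
        ["colony_id", "date", "tmax", "sensor_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    sel = df.groupby(["colony_id", "date"], sort=True).head(1).copy()
    sel["amplitude"] = sel["tmax"] - sel["tmin"]
    cols = ["colony_id", "date", "sensor_id", "tmax", "tmin", "tmean", "amplitude",
            "n_samples", "partial"]
    return sel[cols].reset_index(drop=True)


def classify_brood_days(
    daily: pd.DataFrame, thresholds: DetectionThresholds = DetectionThresholds()
) -> pd.DataFrame:
    """Call brood days: daily max >= 32 degC AND amplitude <= 2 degC (both
    comparisons inclusive). Optionally drops flagged partial days."""
    df = daily.copy()
    if not thresholds.include_partial_days:
        df = df[~df["partial"]].copy()
    df["is_brood"] = (df["tmax"] >= thresholds.t_brood) & (
        df["amplitude"] <= thresholds.amp_max
    )
    return df[["colony_id", "date", "is_brood"]].reset_index(drop=True)


def _runs(dates: np.ndarray, flags: np.ndarray) -> list[tuple[int, int]]:
    """(start_index, length) of maximal runs of True over strictly
    consecutive calendar days; a missing day breaks a run."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(flags):
        gap = i > 0 and (dates[i] - dates[i - 1]) != np.timedelta64(1, "D")
        if start is not None and (not flag or gap):
            runs.append((start, i - start))
            start = None
        if flag and start is None:
            start = i
    if start is not None:
        runs.append((start, len(flags) - start))
    return runs


def detect_onset(
    calls: pd.DataFrame, min_run: int = 3
) -> pd.Timestamp | None:
    """First day of the earliest run of >= *min_run* consecutive brood days
    for a single colony; ``None`` when no such run exists."""
    df = calls.sort_values("date")
    dates = df["date"].to_numpy(dtype="datetime64[D]")
    flags = df["is_brood"].to_numpy(dtype=bool)
    for start, length in _runs(dates, flags):
        if length >= min_run:
            return pd.Timestamp(dates[start])
    return None


def detect_death(daily: pd.DataFrame, t_dead: float = 17.0) -> pd.Timestamp | None:
    """First day of the terminal run with daily max <= *t_dead* extending
    unbroken to the last observed day; ``None`` if the colony recovers or
    the series ends warm."""
    df = daily.sort_values("date")
    dates = df["date"].to_numpy(dtype="datetime64[D]")
    cold = (df["tmax"] <= t_dead).to_numpy(dtype=bool)
    if not cold[-1]:
        return None
    runs = _runs(dates, cold)
    start, length = runs[-1]
    if start + length != len(cold):  # a gap separates the last cold spell from the end
        return None
    return pd.Timestamp(dates[start])


def build_survival_records(
    onsets: dict[str, pd.Timestamp | None],
    deaths: dict[str, pd.Timestamp | None],
    start_date: dt.date,
    end_date: dt.date,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Censored event-time rows for the brood-onset survival analysis.

    Event = 1 at the onset day when brood rearing started before any death;
    otherwise the colony is censored at its death day (cause
    ``death/weak``) or at the experiment's final day (``experiment_end``).
    When onset and death fall on the same day the colony is treated as too
    weak and censored. Day index 1 = *start_date*.
    """
    required = {"colony_id", "temp_regime", "light_regime", "origin_swarm", "brood_at_start"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariates missing columns: {sorted(missing)}")
    if covariates[list(required)].isna().any().any():
        bad = covariates.loc[covariates[list(required)].isna().any(axis=1), "colony_id"]
        raise ValueError(f"incomplete covariates for colonies: {list(bad)}")

    def day_index(ts: pd.Timestamp) -> int:
        return (ts.date() - start_date).days + 1

    end_index = (end_date - start_date).days + 1
    rows = []
    for _, cov in covariates.iterrows():
        cid = cov["colony_id"]
        onset = onsets.get(cid)
        death = deaths.get(cid)
        if onset is not None and (death is None or onset < death):
            time, event, cause = day_index(onset), 1, "none"
        elif death is not None:
            time, event, cause = day_index(death), 0, "death/weak"
        else:
            time, event, cause = end_index, 0, "experiment_end"
        rows.append(
            {
                "colony_id": cid,
                "time": time,
                "event": event,
                "censor_cause": cause,
                "temp_regime": cov["temp_regime"],
                "light_regime": cov["light_regime"],
                "origin_swarm": bool(cov["origin_swarm"]),
                "brood_at_start": bool(cov["brood_at_start"]),
            }
        )
    return pd.DataFrame(rows)


def proportion_brood_days(
    calls: pd.DataFrame, death_day: pd.Timestamp | None
) -> tuple[int, int, float]:
    """(n_brood, n_total, fraction) over the days strictly before death
    (all observed days when the colony never died). A zero denominator
    yields ``nan``."""
    df = calls
    if death_day is not None:
        df = df[df["date"] < death_day]
    n_total = len(df)
    n_brood = int(df["is_brood"].sum())
    fraction = n_brood / n_total if n_total else float("nan")
    return n_brood, n_total, fraction


def analyze_colony(
    samples: pd.DataFrame,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> dict:
    """Run the full detection chain for one colony's telemetry.

    Returns a dict with the selected daily stats, brood-day calls, onset
    and death timestamps, and the brood-day proportion.
    """
    stats = daily_stats(samples)
    daily = select_daily_max_sensor(stats)
    calls = classify_brood_days(daily, thresholds)
    death = detect_death(daily, thresholds.t_dead)
    # days at/after death cannot count as brood activity
    calls_alive = calls if death is None else calls[calls["date"] < death].copy()
    onset = detect_onset(calls_alive, thresholds.min_run)
    n_brood, n_total, fraction = proportion_brood_days(calls, death)
    return {
        "daily": daily,
        "calls": calls,
        "onset": onset,
        "death": death,
        "n_brood_days": n_brood,
        "n_days": n_total,
        "brood_fraction": fraction,
    }
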