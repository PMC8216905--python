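"""Chamber environment scenarios: temperature regimes and photoperiod regimes.

The experiment crosses two temperature regimes with three light regimes:

* ``current`` — weekly mean air temperatures from a long-term daily
  climatology (two-step averaging: per-year daily means, then across
  years), binned into 52 calendar weeks anchored at January 1 (weeks 1-51
  are 7-day blocks, week 52 spans the last nine calendar days of the
  366-day calendar), with a triangular daily cycle of amplitude +-3 degC
  (minimum at 00:00, maximum at 12:00, 0.5 degC hourly steps).
* ``future`` — the same weekly means plus a +4 degC warming offset
  (RCP8.5-like end-of-century scenario).

Light regimes: constant darkness (``CD``), and sunrise-to-sunset light at a
central-European (``CEP``) or northern-European (``NEP``) reference site,
with one-hour linear dawn/dusk ramps ending exactly at sunrise and sunset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .solar import SNASA, WURZBURG, Site, SunTimes, sunrise_sunset

__all__ = [
    "DailyClimatology",
    "WeeklyRegime",
    "HourlyTemperatureProfile",
    "PhotoperiodSchedule",
    "Site",
    "WURZBURG",
    "SNASA",
    "EXPERIMENT_START",
    "EXPERIMENT_END",
    "build_daily_climatology",
    "sinusoidal_climatology",
    "build_weekly_means",
    "apply_warming_offset",
    "expand_hourly",
    "calendar_week",
    "experiment_weekly_means",
    "build_photoperiod_schedule",
    "day_length",
    "sunrise_sunset",
]

#: Date the plants and colonies entered the chambers.
EXPERIMENT_START = dt.date(2017, 11, 14)
#: Date the experiment ended (mid-spring).
EXPERIMENT_END = dt.date(2018, 4, 16)

# 366-day calendar (leap-year ordering) used for the climatology index.
_CAL_DAYS: list[str] = [
    f"{m:02d}-{d:02d}"
    for m in range(1, 13)
    for d in range(1, [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1] + 1)
]


@dataclass(frozen=True)
class DailyClimatology:
    """Mean temperature for each of the 366 calendar days (``MM-DD`` keys)."""

    mean_temp: pd.Series  # index: MM-DD strings in calendar order

    def __post_init__(self) -> None:
        s = self.mean_temp
        if list(s.index) != _CAL_DAYS:
            raise ValueError("climatology must cover all 366 calendar days in order")
        if not np.all(np.isfinite(s.to_numpy(dtype=float))):
            raise ValueError("climatology contains non-finite temperatures")


@dataclass(frozen=True)
class WeeklyRegime:
    """52 weekly mean temperatures for one regime (current or future)."""

    weekly_mean: np.ndarray  # degC, index 0 -> week 1
    regime_label: str = "current"
    warming_offset: float = 0.0

    def __post_init__(self) -> None:
        wm = np.asarray(self.weekly_mean, dtype=float)
        if wm.shape != (52,) or not np.all(np.isfinite(wm)):
            raise ValueError("weekly_mean must be 52 finite values")
        object.__setattr__(self, "weekly_mean", wm)


@dataclass(frozen=True)
class HourlyTemperatureProfile:
    """Hourly chamber setpoints with experiment-week numbering."""

    table: pd.DataFrame  # columns: timestamp, setpoint_c, experiment_week
    regime_label: str

    @property
    def start(self) -> dt.datetime:
        return self.table["timestamp"].iloc[0].to_pydatetime()

    def setpoints(self) -> pd.Series:
        return self.table.set_index("timestamp")["setpoint_c"]


def build_daily_climatology(daily_records: pd.DataFrame) -> DailyClimatology:
    """Average a multi-year daily record into a 366-day climatology.

    Averaging is two-step: first the mean of each calendar day within each
    year, then the mean of those per-year values across years (so a year
    with denser records does not dominate). Feb 29 is averaged over leap
    years only.

    Parameters
    ----------
    daily_records : DataFrame
        Columns ``date`` (datetime-like) and ``temp_c``.
    """
    if daily_records.empty:
        raise ValueError("daily_records is empty")
    df = daily_records.copy()
    df["date"] = pd.to_datetime(df["date"])
    temps = df["temp_c"].to_numpy(dtype=float)
    if not np.all(np.isfinite(temps)):
        raise ValueError("daily_records contains non-finite temperatures")
    df["calendar_day"] = df["date"].dt.strftime("%m-%d")
    df["year"] = df["date"].dt.year
    per_year = df.groupby(["calendar_day", "year"])["temp_c"].mean()
    clim = per_year.groupby("calendar_day").mean()
    missing = sorted(set(_CAL_DAYS) - set(clim.index))
    if missing:
        raise ValueError(f"no observations for calendar day(s): {', '.join(missing)}")
    return DailyClimatology(mean_temp=clim.reindex(_CAL_DAYS))


def sinusoidal_climatology(
    mean: float = 9.2, amplitude: float = 9.0, phase_day: float = 15.0
) -> DailyClimatology:
    """Packaged Wuerzburg-like stand-in climatology.

    ``T(d) = mean - amplitude * cos(2*pi*(d - phase_day)/365.25)`` with *d*
    the 366-calendar day-of-year: coldest in mid-January, warmest in
    mid-July. Any CSV climatology can replace it.
    """
    d = np.arange(1, 367, dtype=float)
    temps = mean - amplitude * np.cos(2 * np.pi * (d - phase_day) / 365.25)
    return DailyClimatology(mean_temp=pd.Series(temps, index=_CAL_DAYS))


def build_weekly_means(clim: DailyClimatology) -> WeeklyRegime:
    """Bin a 366-day climatology into 52 calendar weeks anchored at Jan 1.

    Weeks 1-51 are consecutive 7-day blocks; week 52 is the mean of the
    last nine calendar days (366 - 51*7 = 9).
    """
    vals = clim.mean_temp.to_numpy(dtype=float)
    weekly = np.empty(52)
    weekly[:51] = vals[: 51 * 7].reshape(51, 7).mean(axis=1)
    weekly[51] = vals[51 * 7 :].mean()
    return WeeklyRegime(weekly_mean=weekly, regime_label="current", warming_offset=0.0)


def apply_warming_offset(regime: WeeklyRegime, offset: float) -> WeeklyRegime:
    """Shift every weekly mean by *offset* degC (the warming scenario uses +4)."""
    label = "future" if offset == 4 else regime.regime_label
    return replace(
        regime,
        weekly_mean=regime.weekly_mean + offset,
        regime_label=label,
        warming_offset=regime.warming_offset + offset,
    )


def calendar_week(date: dt.date) -> int:
    """Week number 1-52 of the Jan-1-anchored calendar (week 52 holds 9-10 days)."""
    doy = date.timetuple().tm_yday
    return min((doy - 1) // 7 + 1, 52)


def experiment_weekly_means(
    regime: WeeklyRegime,
    start: dt.date,
    n_weeks: int,
    week_anchor: str = "start",
) -> np.ndarray:
    """Weekly mean setpoints along the experiment's own week numbering.

    With ``week_anchor="start"`` (default) experiment week *i* is the 7-day
    block beginning ``start + 7*(i-1)`` days and takes the weekly mean of
    the Jan-1 calendar week containing that block's first day. With
    ``"calendar"`` the same mapping is used day by day, so the value can
    change mid-block; this helper then reports the block's first-day value.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    out = np.empty(n_weeks)
    for i in range(n_weeks):
        day0 = start + dt.timedelta(days=7 * i)
        out[i] = regime.weekly_mean[calendar_week(day0) - 1]
    return out


def expand_hourly(
    regime: WeeklyRegime,
    start: dt.datetime | dt.date,
    n_weeks: int,
    daily_amplitude: float = 3.0,
    week_anchor: str = "start",
) -> HourlyTemperatureProfile:
    """Expand weekly means into hourly setpoints with the triangular daily cycle.

    Within every day the setpoint is ``weekly_mean - daily_amplitude`` at
    00:00, rises in equal hourly steps (0.5 degC for the default 3 degC
    amplitude) to ``weekly_mean + daily_amplitude`` at 12:00, and falls back
    symmetrically; the weekly mean changes only at the first day of a week
    at 00:00. The 24 hourly values of any full day average exactly to the
    governing weekly mean.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if isinstance(start, dt.datetime):
        if start.time() != dt.time():
            raise ValueError("start must be at 00:00 of a week's first day")
        start_date = start.date()
    else:
        start_date = start
    if week_anchor not in ("start", "calendar"):
        raise ValueError(f"unknown week_anchor: {week_anchor!r}")

    step = daily_amplitude / 6.0  # 12 equal steps from min to max
    hours = np.arange(24)
    day_offsets = np.where(hours <= 12, -daily_amplitude + step * hours,
                           daily_amplitude - step * (hours - 12))

    n_days = 7 * n_weeks
    dates = [start_date + dt.timedelta(days=i) for i in range(n_days)]
    if week_anchor == "start":
        block_first = [start_date + dt.timedelta(days=7 * (i // 7)) for i in range(n_days)]
        day_means = np.array([regime.weekly_mean[calendar_week(d) - 1] for d in block_first])
    else:
        day_means = np.array([regime.weekly_mean[calendar_week(d) - 1] for d in dates])
    exp_week = np.arange(n_days) // 7 + 1

    timestamps = pd.date_range(
        dt.datetime.combine(start_date, dt.time()), periods=n_days * 24, freq="h"
    )
    setpoints = np.repeat(day_means, 24) + np.tile(day_offsets, n_days)
    table = pd.DataFrame(
        {
            "timestamp": timestamps,
            "setpoint_c": setpoints,
            "experiment_week": np.repeat(exp_week, 24),
        }
    )
    return HourlyTemperatureProfile(table=table, regime_label=regime.regime_label)


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """Per-day sunrise/sunset and the resulting light-fraction function.

    For ``CD`` the light fraction is identically zero. For ``CEP``/``NEP``
    the lamps ramp linearly from 0 to 1 over the hour ending at sunrise,
    hold full intensity, and ramp from 1 to 0 over the hour ending at
    sunset, emulating dawn and dusk.
    """

    regime_label: str  # CD | CEP | NEP
    dates: tuple[dt.date, ...]
    sun: dict = field(repr=False)  # date -> SunTimes (empty for CD)
    ramp_h: float = 1.0

    def _check_date(self, date: dt.date) -> None:
        if date < self.dates[0] or date > self.dates[-1]:
            raise ValueError(f"date {date} outside schedule range")

    def sun_times(self, date: dt.date) -> SunTimes | None:
        self._check_date(date)
        return self.sun.get(date)

    def light_fraction(self, when: dt.datetime) -> float:
        """Dimensionless lamp intensity in [0, 1] at clock time *when*."""
        self._check_date(when.date())
        if self.regime_label == "CD":
            return 0.0
        st = self.sun[when.date()]
        if st.polar or st.sunrise is None:
            return 0.0  # polar night; polar day does not occur in this window
        ramp = dt.timedelta(hours=self.ramp_h)
        if when <= st.sunrise - ramp or when >= st.sunset:
            return 0.0
        if when < st.sunrise:
            return (when - (st.sunrise - ramp)) / ramp
        if when <= st.sunset - ramp:
            return 1.0
        return (st.sunset - when) / ramp

    def to_table(self, round_minutes: bool = True) -> pd.DataFrame:
        """Schedule table (date, sunrise, sunset, day_length_h); times rounded
        to the nearest minute for output, unrounded internally."""
        rows = []
        for d in self.dates:
            st = self.sun.get(d)
            if st is None or st.sunrise is None:
                rows.append({"date": d, "sunrise": None, "sunset": None, "day_length_h": 0.0})
                continue
            sr, ss = st.sunrise, st.sunset
            if round_minutes:
                sr = (sr + dt.timedelta(seconds=30)).replace(second=0, microsecond=0)
                ss = (ss + dt.timedelta(seconds=30)).replace(second=0, microsecond=0)
            rows.append(
                {"date": d, "sunrise": sr, "sunset": ss, "day_length_h": st.day_length_h}
            )
        return pd.DataFrame(rows)


def build_photoperiod_schedule(
    regime_label: str,
    site: Site | None,
    dates: list[dt.date] | tuple[dt.date, dt.date],
    ramp_h: float = 1.0,
) -> PhotoperiodSchedule:
    """Build the light program for one regime over *dates*.

    *dates* may be an explicit list or an inclusive ``(first, last)`` pair.
    ``CD`` needs no site; ``CEP``/``NEP`` require one.
    """
    if regime_label not in ("CD", "CEP", "NEP"):
        raise ValueError(f"unknown light regime: {regime_label!r}")
    if isinstance(dates, tuple) and len(dates) == 2 and isinstance(dates[0], dt.date):
        first, last = dates
        dates = [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]
    dates = tuple(dates)
    if regime_label == "CD":
        return PhotoperiodSchedule(regime_label="CD", dates=dates, sun={}, ramp_h=ramp_h)
    if site is None:
        raise ValueError(f"{regime_label} regime requires a site")
    sun = {d: sunrise_sunset(site, d) for d in dates}
    return PhotoperiodSchedule(regime_label=regime_label, dates=dates, sun=sun, ramp_h=ramp_h)


def day_length(schedule: PhotoperiodSchedule, date: dt.date) -> float:
    """Sunset minus sunrise in hours for *date*; 0 under constant darkness."""
    schedule._check_date(date)
    if schedule.regime_label == "CD":
        return 0.0
    return schedule.sun[date].day_length_h
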