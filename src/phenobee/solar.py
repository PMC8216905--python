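"""Sunrise/sunset times from the NOAA solar calculator algorithm.

The chamber light programs follow local sunrise and sunset at a reference
site, so the solar position is computed the same way the NOAA calculator
does: Julian-century polynomial series for the sun's mean elements, the
equation of time from the obliquity and eccentricity, and the hour angle at
a zenith of 90.833 deg (34' refraction + 16' solar semidiameter).
Accuracy is well under a minute at mid latitudes, which is far below the
one-minute rounding used for the light schedules.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = ["Site", "SunTimes", "WURZBURG", "SNASA", "sunrise_sunset", "solar_noon"]

#: Zenith angle (degrees) defining sunrise/sunset: 90 deg + atmospheric
#: refraction (34') + solar semidiameter (16').
SUNRISE_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class Site:
    """A reference location for the photoperiod program.

    Parameters
    ----------
    name : str
        Human-readable site name.
    latitude : float
        Degrees north (negative south). ``|latitude| <= 90``.
    longitude : float
        Degrees east (negative west). ``|longitude| <= 180``.
    utc_offset : float
        Fixed clock offset from UTC in hours. The chamber clock does not
        observe daylight-saving time.
    """

    name: str
    latitude: float
    longitude: float
    utc_offset: float = 1.0

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not abs(self.longitude) <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")


#: Wuerzburg, Germany (49 deg 48' N, 9 deg 55' 48'' E), CET.
WURZBURG = Site("Würzburg", 49.8, 9.93, 1.0)
#: Snåsa, Norway (64 deg 15' N, 12 deg 23' E), CET.
SNASA = Site("Snåsa", 64.25, 12.3833, 1.0)


@dataclass(frozen=True)
class SunTimes:
    """Sunrise/sunset for one site and date, in local clock time."""

    date: dt.date
    sunrise: dt.datetime | None
    sunset: dt.datetime | None
    polar: bool = False  # midnight sun or polar night: no rise/set event

    @property
    def day_length_h(self) -> float:
        if self.sunrise is None or self.sunset is None:
            return 0.0
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _julian_day(date: dt.date) -> float:
    # JD at 00:00 UT; standard Gregorian conversion.
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_geometry(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    eq_center = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    obliq0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = obliq0 + 0.00256 * math.cos(omega)
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))

    y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0rad = math.radians(l0)
    eqtime_min = 4.0 * math.degrees(
        y * math.sin(2 * l0rad)
        - 2.0 * ecc * math.sin(mrad)
        + 4.0 * ecc * y * math.sin(mrad) * math.cos(2 * l0rad)
        - 0.5 * y * y * math.sin(4 * l0rad)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return eqtime_min, decl


def solar_noon(site: Site, date: dt.date) -> dt.datetime:
    """Local clock time of solar transit at *site* on *date*."""
    jd = _julian_day(date) + 0.5 - site.utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0
    eqtime, _ = _sun_geometry(jc)
    noon_min = 720.0 - 4.0 * site.longitude - eqtime + 60.0 * site.utc_offset
    return dt.datetime.combine(date, dt.time()) + dt.timedelta(minutes=noon_min)


def sunrise_sunset(site: Site, date: dt.date) -> SunTimes:
    """Compute local sunrise and sunset for one date.

    Returns a :class:`SunTimes`; at polar latitudes where the sun never
    crosses the 90.833 deg zenith circle the ``polar`` flag is set and both
    times are ``None``.
    """
    # Evaluate the sun's elements at local civil noon; the intra-day drift
    # of declination/EoT is below the schedule's one-minute rounding.
    jd = _julian_day(date) + 0.5 - site.utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0
    eqtime, decl = _sun_geometry(jc)

    lat = math.radians(site.latitude)
    cos_ha = (
        math.cos(math.radians(SUNRISE_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if cos_ha > 1.0 or cos_ha < -1.0:
        return SunTimes(date=date, sunrise=None, sunset=None, polar=True)
    ha_deg = math.degrees(math.acos(cos_ha))

    noon_min = 720.0 - 4.0 * site.longitude - eqtime + 60.0 * site.utc_offset
    midnight = dt.datetime.combine(date, dt.time())
    sunrise = midnight + dt.timedelta(minutes=noon_min - 4.0 * ha_deg)
    sunset = midnight + dt.timedelta(minutes=noon_min + 4.0 * ha_deg)
    return SunTimes(date=date, sunrise=sunrise, sunset=sunset)
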