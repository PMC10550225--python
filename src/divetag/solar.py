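"""Sunrise, solar noon, and sunset from the NOAA solar equations.

All inputs are UTC; longitudes may be given either in [-180, 180] or
[0, 360] degrees east. Accuracy is within a few minutes, which is ample
for windowing dive records by daylight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta, timezone

__all__ = ["SolarEvents", "solar_events", "local_solar_hour", "PolarLatitudeError"]

_ZENITH_OFFICIAL = 90.833  # degrees; includes refraction + solar radius

MAX_LATITUDE = 66.0


class PolarLatitudeError(ValueError):
    """Latitude outside the supported (non-polar) range."""


@dataclass(frozen=True)
class SolarEvents:
    sunrise: datetime
    solar_noon: datetime
    sunset: datetime

    def is_daytime(self, t: datetime) -> bool:
        t = _as_utc(t)
        return self.sunrise <= t <= self.sunset


def _as_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def normalize_lon(lon: float) -> float:
    """Normalize a longitude to [-180, 180)."""
    lon = float(lon) % 360.0
    return lon - 360.0 if lon >= 180.0 else lon


def local_solar_hour(t: datetime, lon: float) -> float:
    """Approximate local solar hour-of-day: UTC + lon/15, in [0, 24)."""
    t = _as_utc(t)
    h = t.hour + t.minute / 60.0 + t.second / 3600.0
    return (h + normalize_lon(lon) / 15.0) % 24.0


def _solar_params(day_of_year: int, hour: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def solar_events(date: _date, lat: float, lon: float) -> SolarEvents:
    """Sunrise, solar noon, and sunset (UTC datetimes) for one day/position.

    Raises
    ------
    PolarLatitudeError
        If ``|lat| >= 66`` degrees, or the sun does not rise/set that day.
    """
    if abs(lat) >= MAX_LATITUDE:
        raise PolarLatitudeError(
            f"latitude {lat} outside supported range |lat| < {MAX_LATITUDE}"
        )
    lon = normalize_lon(lon)
    doy = date.timetuple().tm_yday
    eqtime, decl = _solar_params(doy, 12.0)

    lat_r = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(_ZENITH_OFFICIAL)) / (math.cos(lat_r) * math.cos(decl))
        - math.tan(lat_r) * math.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise PolarLatitudeError(
            f"no sunrise/sunset at lat={lat} on {date} (polar day/night)"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    noon_min = 720.0 - 4.0 * lon - eqtime
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    noon = midnight + timedelta(minutes=noon_min)
    sunrise = midnight + timedelta(minutes=noon_min - 4.0 * ha_deg)
    sunset = midnight + timedelta(minutes=noon_min + 4.0 * ha_deg)
    return SolarEvents(sunrise=sunrise, solar_noon=noon, sunset=sunset)
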