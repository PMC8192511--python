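"""Solar declination / hour-angle geometry for twilight times.

The same closed model serves both sides of the analysis: the tag simulator
emits sunrise/sunset times from it, and the light-based position estimate
inverts it. The sun is "up" above altitude -0.833 deg (refraction plus solar
radius). The equation of time is deliberately omitted so that local solar noon
is exactly 12:00 UTC at longitude 0; tags and inversion share the same clock,
so the simplification cancels along the whole chain.
"""

from __future__ import annotations

import datetime as dt
import math

SUN_ALTITUDE_DEG = -0.833
TROPICAL_YEAR_DAYS = 365.2422
OBLIQUITY_DEG = 23.44


def solar_declination_deg(date: dt.date) -> float:
    """Approximate solar declination for a calendar date (degrees).

    Cosine model with the December solstice pinned near Dec 21 (day-of-year
    offset +10); accurate to ~1 deg, which is well inside tag twilight noise.
    """
    n = date.timetuple().tm_yday
    return -OBLIQUITY_DEG * math.cos(2.0 * math.pi * (n + 10) / TROPICAL_YEAR_DAYS)


def sunrise_hour_angle_deg(lat_deg: float, decl_deg: float) -> float | None:
    """Hour angle (degrees) between local noon and sunrise/sunset.

    Returns None during polar day or polar night (no twilight event).
    """
    phi = math.radians(lat_deg)
    delta = math.radians(decl_deg)
    cos_omega = (
        math.sin(math.radians(SUN_ALTITUDE_DEG)) - math.sin(phi) * math.sin(delta)
    ) / (math.cos(phi) * math.cos(delta))
    if cos_omega < -1.0 or cos_omega > 1.0:
        return None
    return math.degrees(math.acos(cos_omega))


def twilight_times_utc(
    date: dt.date, lat_deg: float, lon_deg: float
) -> tuple[dt.datetime, dt.datetime] | None:
    """(sunrise, sunset) as UTC datetimes, or None above the polar circles.

    Local solar noon falls at 12:00 - lon/15 h UTC; sunrise and sunset sit
    symmetrically at +- hour_angle/15 h around it.
    """
    omega = sunrise_hour_angle_deg(lat_deg, solar_declination_deg(date))
    if omega is None:
        return None
    noon_utc_h = 12.0 - lon_deg / 15.0
    half_day_h = omega / 15.0
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    sunrise = base + dt.timedelta(hours=noon_utc_h - half_day_h)
    sunset = base + dt.timedelta(hours=noon_utc_h + half_day_h)
    return sunrise, sunset
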