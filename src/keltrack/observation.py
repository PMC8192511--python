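"""From raw tag records to daily observations and likelihood surfaces.

Each UTC day with data contributes: the maximum depth, the mean temperature
of samples shallower than 20 m (the "SST" the tag saw), and — when twilight
times exist — a light-based position estimate. The daily likelihood over the
state grid is the cellwise product of independent components:

* longitude: Gaussian around the light longitude (sd ``sigma_lon_deg``);
* latitude: Gaussian around the light latitude (sd ``sigma_lat_deg``), used
  only when the day-length inversion is informative (dropped within an
  equinox window where day length carries no latitude signal);
* SST: Gaussian between tag SST and the monthly field (sd ``sigma_sst_c``);
* depth: an indicator that the water is at least as deep as the day's
  maximum depth (with a small tolerance for pressure-sensor error).

A missing component contributes a uniform factor. Anchors (release, pop-up)
are Gaussian surfaces in km around a known position.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from keltrack import solar
from keltrack.errors import KeltrackError, ShapeError
from keltrack.geo import great_circle_km
from keltrack.spatial_grid import StateGrid
from keltrack.tag_io import TagSeries

SURFACE_SST_MAX_DEPTH_M = 20.0


@dataclass
class LikelihoodParams:
    sigma_lon_deg: float = 0.5
    sigma_lat_deg: float = 1.5
    sigma_sst_c: float = 0.7
    equinox_window_days: int = 10
    min_day_length_offset_min: float = 10.0
    bathy_tol_m: float = 10.0
    popup_sd_km: float = 10.0


@dataclass
class DailyObservation:
    date: dt.date
    max_depth_m: float | None = None
    sst_c: float | None = None
    light_lon_deg: float | None = None
    light_lat_deg: float | None = None
    lat_usable: bool = False


@dataclass
class LikelihoodSurface:
    date: dt.date | None
    values: np.ndarray
    components: tuple[str, ...] = ()
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.degenerate = not np.any(self.values > 0)


def _days_to_equinox(date: dt.date) -> int:
    """Days to the nearest March 20 / September 22 equinox."""
    best = 999
    for y in (date.year - 1, date.year, date.year + 1):
        for eq in (dt.date(y, 3, 20), dt.date(y, 9, 22)):
            best = min(best, abs((date - eq).days))
    return best


def light_position(
    sunrise: dt.datetime,
    sunset: dt.datetime,
    date: dt.date,
    equinox_window_days: int = 10,
    min_day_length_offset_min: float = 10.0,
) -> tuple[float, float | None, bool]:
    """Invert twilight times to (lon, lat, lat_usable).

    Longitude comes from the local-noon offset (15 deg per hour); latitude
    from the day length via the standard hour-angle inversion at the date's
    solar declination. Near the equinoxes the day length is ~12 h everywhere
    and carries no latitude information: the latitude is still returned when
    solvable, but flagged unusable.
    """
    if sunset <= sunrise:
        sunset = sunset + dt.timedelta(days=1)
    midpoint = sunrise + (sunset - sunrise) / 2
    day0 = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    noon_offset_h = (midpoint - day0).total_seconds() / 3600.0 - 12.0
    lon = -15.0 * noon_offset_h
    day_length_h = (sunset - sunrise).total_seconds() / 3600.0

    decl = solar.solar_declination_deg(date)
    omega = math.radians(day_length_h / 2.0 * 15.0)
    # solve sin(phi) sin(delta) + cos(phi) cos(delta) cos(omega) = sin(h0)
    a = math.sin(math.radians(decl))
    b = math.cos(math.radians(decl)) * math.cos(omega)
    c = math.sin(math.radians(solar.SUN_ALTITUDE_DEG))
    r = math.hypot(a, b)
    lat: float | None = None
    if r > 1e-12 and abs(c / r) <= 1.0:
        psi = math.atan2(b, a)
        cands = [
            math.degrees(math.asin(c / r) - psi) % 360.0,
            math.degrees(math.pi - math.asin(c / r) - psi) % 360.0,
        ]
        cands = [((x + 180.0) % 360.0) - 180.0 for x in cands]
        in_range = [x for x in cands if -89.0 <= x <= 89.0]
        if len(in_range) == 1:
            lat = in_range[0]
        elif len(in_range) == 2:
            # long summer days -> same hemisphere as the sun; short days -> opposite
            want = math.copysign(1.0, decl) * math.copysign(1.0, day_length_h - 12.0)
            same = [x for x in in_range if math.copysign(1.0, x) == want]
            lat = same[0] if same else min(in_range, key=abs)

    usable = (
        lat is not None
        and _days_to_equinox(date) > equinox_window_days
        and abs(day_length_h - 12.0) * 60.0 > min_day_length_offset_min
    )
    return lon, lat, usable


def daily_observations(
    series: TagSeries, params: LikelihoodParams | None = None
) -> list[DailyObservation]:
    """Per-UTC-day summaries of a tag record (one entry per day with samples)."""
    params = params or LikelihoodParams()
    out: list[DailyObservation] = []
    if len(series.samples) == 0:
        return out
    twl = {row["date"]: row for _, row in series.twilights.iterrows()}
    grouped = series.samples.groupby(series.samples["timestamp"].dt.date, sort=True)
    for date, day in grouped:
        obs = DailyObservation(date=date)
        obs.max_depth_m = float(day["depth_m"].max())
        shallow = day.loc[day["depth_m"] < SURFACE_SST_MAX_DEPTH_M, "temperature_c"].dropna()
        if len(shallow):
            obs.sst_c = float(shallow.mean())
        row = twl.get(date)
        if row is not None and not (pd.isna(row["sunrise_utc"]) or pd.isna(row["sunset_utc"])):
            lon, lat, usable = light_position(
                row["sunrise_utc"].to_pydatetime(),
                row["sunset_utc"].to_pydatetime(),
                date,
                params.equinox_window_days,
                params.min_day_length_offset_min,
            )
            obs.light_lon_deg = lon
            obs.light_lat_deg = lat
            obs.lat_usable = usable
        out.append(obs)
    return out


def daily_likelihood(
    obs: DailyObservation, grid: StateGrid, params: LikelihoodParams | None = None
) -> LikelihoodSurface:
    """Cellwise product of the light / SST / depth components for one day."""
    params = params or LikelihoodParams()
    values = np.ones(grid.n_states)
    components: list[str] = []

    if obs.light_lon_deg is not None:
        dlon = ((grid.lon - obs.light_lon_deg + 180.0) % 360.0) - 180.0
        values *= np.exp(-0.5 * (dlon / params.sigma_lon_deg) ** 2)
        components.append("light_lon")
        if obs.lat_usable and obs.light_lat_deg is not None:
            dlat = grid.lat - obs.light_lat_deg
            values *= np.exp(-0.5 * (dlat / params.sigma_lat_deg) ** 2)
            components.append("light_lat")

    if obs.sst_c is not None:
        month = obs.date.month
        dsst = grid.sst(month) - obs.sst_c
        values *= np.exp(-0.5 * (dsst / params.sigma_sst_c) ** 2)
        components.append("sst")

    if obs.max_depth_m is not None and obs.max_depth_m > 0:
        feasible = grid.bathymetry + params.bathy_tol_m >= obs.max_depth_m
        values *= feasible
        components.append("depth")

    return LikelihoodSurface(date=obs.date, values=values, components=tuple(components))


def anchor_surface(grid: StateGrid, lat: float, lon: float, sd_km: float) -> LikelihoodSurface:
    """Gaussian anchor around a known position (release or pop-up).

    sd_km = 0 yields a point mass at the nearest ocean state; a position on
    land is likewise pulled to the nearest ocean state.
    """
    d = great_circle_km(lat, lon, grid.lat, grid.lon)
    if sd_km <= 0:
        values = np.zeros(grid.n_states)
        values[int(np.argmin(d))] = 1.0
    else:
        values = np.exp(-0.5 * (d / sd_km) ** 2)
        if not np.any(values > 0):
            values[int(np.argmin(d))] = 1.0
    surf = LikelihoodSurface(date=None, values=values, components=("anchor",))
    if float(d.min()) > 5000.0:
        raise KeltrackError("anchor location is far outside the grid domain")
    return surf
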