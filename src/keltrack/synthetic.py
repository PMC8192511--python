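"""Synthetic ocean, fish tracks and tag records.

The generator emulates the statistical structure the geolocation chain
assumes about PSAT deployments on post-spawned Atlantic salmon:

* a North-Atlantic-like SST field — strictly colder poleward, a seasonal
  cosine cycle, spatial noise — over a basin with a shelf along one coast;
* directed migration as a biased random walk towards a distant front-like
  target at tens of km per day;
* surface-oriented depth use (80% of samples shallower than 10 m by default)
  with Poisson-count deeper dives; SST sampled at the true position plus
  sensor noise; twilight times from solar geometry plus noise in minutes;
  i.i.d. per-sample transmission dropout (default 0.31, i.e. ~69% of the
  archive recovered); pop-up on the programmed date or after 4-5 days at
  constant depth (the tags' mortality / premature-detachment rule).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from keltrack import solar
from keltrack.errors import ConfigError, KeltrackError, ValidationError
from keltrack.geo import destination_point, great_circle_km, initial_bearing_deg, wrap_lon
from keltrack.tag_io import EnvironmentGrid, TagDeployment, TagSeries

KM_PER_DEG_LAT = 111.19


@dataclass
class EnvironmentParams:
    """Synthetic SST / bathymetry model. Units: degrees, deg C, m."""

    lat_min: float = 45.0
    lat_max: float = 75.0
    lon_min: float = -30.0
    lon_max: float = 20.0
    resolution_deg: float = 1.0
    sst_ref_c: float = 12.0          # SST at lat_ref before season/noise
    lat_ref: float = 45.0
    gradient_c_per_deg: float = 0.35  # equator-to-pole cooling
    seasonal_amplitude_c: float = 2.5
    warmest_month: int = 7
    noise_sd_c: float = 0.3
    coast_lon_deg: float | None = 15.0  # land east of this longitude; None = all ocean
    shelf_width_deg: float = 3.0
    basin_depth_m: float = 3000.0
    min_depth_m: float = 50.0


@dataclass
class MovementParams:
    """Daily biased random walk towards a target (a front-like feeding area)."""

    speed_km_per_day: float = 40.0
    speed_sd_km: float = 8.0
    bias: float = 0.8                 # probability a day's heading points at the target
    target_lat: float = 70.0
    target_lon: float = -5.0


@dataclass
class TagParams:
    """Tag sampling, sensing noise, dropout and release programming."""

    sampling_interval_min: int = 30
    surface_fraction: float = 0.8     # fraction of samples shallower than 10 m
    surface_layer_m: float = 10.0
    dive_rate_per_day: float = 3.0    # Poisson count of deeper excursions
    dive_depth_median_m: float = 80.0
    dive_depth_log_sd: float = 0.7
    sst_noise_sd_c: float = 0.3
    twilight_skew_sd_min: float = 20.0   # dive-induced late sunrise / early sunset
    twilight_clock_sd_min: float = 2.0   # symmetric timing error (shifts noon)
    dropout: float = 0.31
    deployment_days: int = 90
    constant_depth_window_days: int = 5   # tags release after 4 or 5 flat days
    constant_depth_range_m: float = 3.0
    popup_noise_sd_km: float = 5.0
    mortality_day: int | None = None  # force constant depth from this day (testing hook)


@dataclass
class SimulationConfig:
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    movement: MovementParams = field(default_factory=MovementParams)
    tag: TagParams = field(default_factory=TagParams)
    release_lat: float = 58.0
    release_lon: float = 8.0
    release_date: dt.date = dt.date(2010, 5, 1)
    population: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        e, m, t = self.environment, self.movement, self.tag
        if e.resolution_deg <= 0:
            raise ConfigError("resolution must be positive")
        if not 0.0 <= m.bias <= 1.0:
            raise ConfigError("bias must be in [0, 1]")
        if not 0.0 <= t.dropout <= 1.0:
            raise ConfigError("dropout must be in [0, 1]")
        if not 15 <= t.sampling_interval_min <= 60:
            raise ConfigError("sampling interval must be in [15, 60] minutes")
        if t.constant_depth_window_days not in (4, 5):
            raise ConfigError("constant-depth release window must be 4 or 5 days")
        for name, sd in (
            ("noise_sd_c", e.noise_sd_c),
            ("speed_sd_km", m.speed_sd_km),
            ("sst_noise_sd_c", t.sst_noise_sd_c),
            ("twilight_skew_sd_min", t.twilight_skew_sd_min),
            ("twilight_clock_sd_min", t.twilight_clock_sd_min),
            ("popup_noise_sd_km", t.popup_noise_sd_km),
        ):
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class TrueTrack:
    """Ground-truth daily positions for one simulated fish."""

    deployment: TagDeployment
    positions: pd.DataFrame  # columns: date, lat, lon

    @property
    def n_days(self) -> int:
        return len(self.positions)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def generate_environment(config: SimulationConfig) -> EnvironmentGrid:
    """Build the monthly SST / bathymetry / land-mask grid of the simulation.

    Before noise the SST is ``ref - gradient*(lat - lat_ref) +
    A*cos(2*pi*(month - warmest)/12)``: strictly colder poleward, seasonal
    peak-to-trough 2A. Land occupies the band east of ``coast_lon_deg`` and
    the sea floor shoals exponentially onto that shelf.
    """
    e = config.environment
    lat = np.arange(e.lat_min + e.resolution_deg / 2.0, e.lat_max, e.resolution_deg)
    lon = np.arange(e.lon_min + e.resolution_deg / 2.0, e.lon_max, e.resolution_deg)
    if lat.size < 2 or lon.size < 2:
        raise ConfigError("degenerate grid: need at least 2 cells per axis")

    months = np.arange(1, 13)
    seasonal = e.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (months - e.warmest_month) / 12.0
    )
    base = e.sst_ref_c - e.gradient_c_per_deg * (lat - e.lat_ref)
    sst = base[None, :, None] + seasonal[:, None, None] + np.zeros((1, 1, lon.size))
    if e.noise_sd_c > 0:
        sst = sst + _rng(config, 0).normal(0.0, e.noise_sd_c, size=sst.shape)

    if e.coast_lon_deg is None:
        land = np.zeros((lat.size, lon.size), dtype=bool)
        bathy = np.full((lat.size, lon.size), e.basin_depth_m)
    else:
        # gently wiggled meridional coastline, land to the east
        coast = e.coast_lon_deg - 1.5 * np.sin(np.radians(4.0 * lat))
        land = lon[None, :] >= coast[:, None]
        dist_deg = np.maximum(0.0, coast[:, None] - lon[None, :])
        bathy = e.min_depth_m + (e.basin_depth_m - e.min_depth_m) * (
            1.0 - np.exp(-dist_deg / e.shelf_width_deg)
        )
        bathy[land] = 0.0
    return EnvironmentGrid(lat=lat, lon=lon, sst=sst, bathymetry=bathy, land_mask=land)


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------


def simulate_track(env: EnvironmentGrid, config: SimulationConfig) -> TrueTrack:
    """Daily-position biased random walk from the release point.

    Each day the heading is the great-circle bearing to the target with
    probability ``bias``, otherwise uniform; the step length is Gaussian
    around the configured speed (truncated at 0). Steps onto land or out of
    the domain are rejected by resampling the heading.
    """
    m = config.movement
    if not env.is_ocean(config.release_lat, config.release_lon):
        raise ValidationError("release location is on land")
    rng = _rng(config, 1)
    n_days = config.tag.deployment_days
    lats = [config.release_lat]
    lons = [config.release_lon]
    lat_lo, lat_hi = env.lat.min(), env.lat.max()
    lon_lo, lon_hi = env.lon.min(), env.lon.max()
    for _ in range(n_days):
        step = max(0.0, rng.normal(m.speed_km_per_day, m.speed_sd_km))
        placed = False
        for attempt in range(200):
            if attempt == 0 and rng.random() < m.bias:
                heading = initial_bearing_deg(lats[-1], lons[-1], m.target_lat, m.target_lon)
            else:
                heading = rng.uniform(0.0, 360.0)
            la, lo = destination_point(lats[-1], lons[-1], heading, step)
            inside = lat_lo <= la <= lat_hi and lon_lo <= lo <= lon_hi
            if step == 0.0 or (inside and env.is_ocean(la, lo)):
                lats.append(float(la) if step > 0 else lats[-1])
                lons.append(float(lo) if step > 0 else lons[-1])
                placed = True
                break
        if not placed:
            raise KeltrackError("no feasible step: position appears landlocked")
    dates = [config.release_date + dt.timedelta(days=i) for i in range(n_days + 1)]
    deployment = TagDeployment(
        tag_id=f"sim-{config.seed}",
        population=config.population,
        release_date=config.release_date,
        release_lat=config.release_lat,
        release_lon=config.release_lon,
    )
    return TrueTrack(
        deployment=deployment,
        positions=pd.DataFrame({"date": dates, "lat": lats, "lon": lons}),
    )


# ---------------------------------------------------------------------------
# tag record
# ---------------------------------------------------------------------------


def _daily_depths(n: int, t: TagParams, rng: np.random.Generator) -> np.ndarray:
    """Depths for one day's n samples: surface layer + dive blocks.

    The count of sub-surface samples is Binomial(n, 1 - surface_fraction) so
    the surface occupancy is exactly the configured Bernoulli rate; dive
    samples are grouped into Poisson-count bouts sharing a log-normal maximum
    depth with a U-shaped within-bout profile.
    """
    depth = rng.uniform(0.0, t.surface_layer_m, size=n)
    n_deep = rng.binomial(n, 1.0 - t.surface_fraction)
    if n_deep == 0:
        return depth
    n_dives = max(1, rng.poisson(t.dive_rate_per_day))
    splits = np.sort(rng.choice(np.arange(1, n_deep), size=min(n_dives - 1, n_deep - 1), replace=False)) if n_deep > 1 else np.array([], dtype=int)
    blocks = np.split(np.arange(n_deep), splits)
    start = rng.integers(0, n - n_deep + 1) if n > n_deep else 0
    idx = np.arange(start, start + n_deep)
    pos = 0
    for block in blocks:
        m = len(block)
        if m == 0:
            continue
        max_d = max(
            t.surface_layer_m + 1.0,
            float(rng.lognormal(math.log(t.dive_depth_median_m), t.dive_depth_log_sd)),
        )
        u = np.linspace(-1.0, 1.0, m + 2)[1:-1]  # U-shape: deepest mid-bout
        depth[idx[pos : pos + m]] = t.surface_layer_m + (max_d - t.surface_layer_m) * (
            1.0 - u**2 * 0.3
        )
        pos += m
    return depth


def simulate_tag_series(
    track: TrueTrack, env: EnvironmentGrid, config: SimulationConfig
) -> TagSeries:
    """Generate the tag's archived record along a true track.

    Applies, in order: depth sampling, SST observation at the true cell plus
    noise, twilight times from solar geometry plus noise, truncation at the
    programmed pop-up date or at the constant-depth release rule, then
    i.i.d. per-sample dropout. The returned deployment carries the pop-up
    date and the pop-up position with Argos-scale noise.
    """
    t = config.tag
    rng = _rng(config, 2)
    if track.n_days == 0:
        raise ValidationError("empty track")
    per_day = int(round(24 * 60 / t.sampling_interval_min))
    interval = dt.timedelta(minutes=t.sampling_interval_min)

    rows: list[tuple[dt.datetime, float, float]] = []
    twl_rows: list[tuple[dt.date, dt.datetime | None, dt.datetime | None]] = []
    popup_day_idx = track.n_days - 1
    flat_run = 0
    day_ranges: list[float] = []
    for day_idx in range(track.n_days):
        date = track.positions["date"].iloc[day_idx]
        lat = float(track.positions["lat"].iloc[day_idx])
        lon = float(track.positions["lon"].iloc[day_idx])
        depths = _daily_depths(per_day, t, rng)
        if t.mortality_day is not None and day_idx >= t.mortality_day:
            depths = np.full(per_day, 12.0)  # dead fish / expelled tag at fixed depth
        true_sst = env.sst_at(date.month, lat, lon)
        if t.sst_noise_sd_c > 0:
            # day-correlated bias (sensor offset / climatology mismatch) plus
            # per-sample jitter; the bias is what survives the daily mean
            day_bias = rng.normal(0.0, t.sst_noise_sd_c)
            temps = true_sst + day_bias + rng.normal(0.0, t.sst_noise_sd_c, size=per_day)
        else:
            temps = np.full(per_day, true_sst)
        base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
        for k in range(per_day):
            rows.append((base + k * interval, float(depths[k]), float(temps[k])))

        tw = solar.twilight_times_utc(date, lat, lon)
        if tw is None:
            twl_rows.append((date, None, None))
        else:
            # A surface-diving fish sees first light late and last light early:
            # half-normal skew shrinks the apparent day (degrading latitude),
            # while the symmetric clock error is what moves apparent noon.
            skew_r = abs(rng.normal(0.0, t.twilight_skew_sd_min))
            skew_s = abs(rng.normal(0.0, t.twilight_skew_sd_min))
            clock = rng.normal(0.0, t.twilight_clock_sd_min, size=2)
            sr = tw[0] + dt.timedelta(minutes=skew_r + float(clock[0]))
            ss = tw[1] + dt.timedelta(minutes=-skew_s + float(clock[1]))
            if ss <= sr:  # pathological shrink: drop the twilight pair
                twl_rows.append((date, None, None))
            else:
                twl_rows.append((date, sr, ss))

        day_ranges.append(float(depths.max() - depths.min()))
        flat_run = flat_run + 1 if day_ranges[-1] < t.constant_depth_range_m else 0
        if flat_run >= t.constant_depth_window_days:
            popup_day_idx = day_idx
            break

    n_days_kept = popup_day_idx + 1
    samples = pd.DataFrame(rows, columns=["timestamp", "depth_m", "temperature_c"])
    samples["timestamp"] = pd.to_datetime(samples["timestamp"], utc=True)
    keep = rng.random(len(samples)) >= t.dropout
    samples = samples.loc[keep].reset_index(drop=True)
    twilights = pd.DataFrame(twl_rows[:n_days_kept], columns=["date", "sunrise_utc", "sunset_utc"])
    twilights["sunrise_utc"] = pd.to_datetime(twilights["sunrise_utc"], utc=True)
    twilights["sunset_utc"] = pd.to_datetime(twilights["sunset_utc"], utc=True)

    pop_lat = float(track.positions["lat"].iloc[popup_day_idx])
    pop_lon = float(track.positions["lon"].iloc[popup_day_idx])
    if t.popup_noise_sd_km > 0:
        pop_lat += rng.normal(0.0, t.popup_noise_sd_km / KM_PER_DEG_LAT)
        pop_lon += rng.normal(
            0.0, t.popup_noise_sd_km / (KM_PER_DEG_LAT * math.cos(math.radians(pop_lat)))
        )
    d = track.deployment
    deployment = TagDeployment(
        tag_id=d.tag_id,
        population=d.population,
        release_date=d.release_date,
        release_lat=d.release_lat,
        release_lon=d.release_lon,
        popup_date=track.positions["date"].iloc[popup_day_idx],
        popup_lat=float(np.clip(pop_lat, -90.0, 90.0)),
        popup_lon=float(wrap_lon(pop_lon)),
    )
    return TagSeries(deployment=deployment, samples=samples, twilights=twilights)


def simulate_deployment(
    config: SimulationConfig, env: EnvironmentGrid | None = None
) -> tuple[EnvironmentGrid, TrueTrack, TagSeries]:
    """Convenience wrapper: environment (unless given) + track + tag record."""
    if env is None:
        env = generate_environment(config)
    track = simulate_track(env, config)
    series = simulate_tag_series(track, env, config)
    return env, track, series
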