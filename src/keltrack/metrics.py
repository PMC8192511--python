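"""Migration and behaviour summaries.

Distances "along a straight line" are great-circle km (R = 6371 km). Weekly
distance profiles average the daily distance from the release location over
consecutive 7-day blocks since release; the migration-speed regression fits
weekly mean distance against week index for the first weeks after release
(default 11, the time most populations need to reach their principal feeding
areas). Depth use reports the fraction of samples deeper than a threshold
(10 m: the surface-orientation benchmark), with a post-migration preset
selecting samples strictly more than 77 days (11 weeks) after release.
Thermal niche summarises all retained temperature samples per group and
calendar month — deliberately not restricted to the <20 m SST filter used
for geolocation, because it describes where the fish resided.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from keltrack.errors import KeltrackError
from keltrack.geo import great_circle_km
from keltrack.tag_io import TagSeries

POST_MIGRATION_DAYS = 77  # strictly more than 11 weeks after release
DEPTH_THRESHOLD_M = 10.0
REGRESSION_MAX_WEEK = 11


def great_circle_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points (haversine, R = 6371 km)."""
    return float(great_circle_km(lat1, lon1, lat2, lon2))


def weekly_distance_profile(
    track: pd.DataFrame, release_lat: float, release_lon: float
) -> pd.DataFrame:
    """Weekly mean distance from the release location along a daily mean track.

    Weeks are consecutive 7-day blocks from the release date (week 1 = days
    1-7). Returns columns week, mean_km, n_days; a track shorter than 7 days
    yields a single partial week flagged in the ``partial`` column.
    """
    if len(track) == 0:
        raise KeltrackError("empty track")
    d0 = track["date"].iloc[0]
    days = np.array([(d - d0).days for d in track["date"]])
    dist = great_circle_km(
        track["mean_lat"].to_numpy(), track["mean_lon"].to_numpy(), release_lat, release_lon
    )
    sel = days >= 1
    week = (days[sel] - 1) // 7 + 1
    df = pd.DataFrame({"week": week, "km": dist[sel]})
    out = df.groupby("week", as_index=False).agg(mean_km=("km", "mean"), n_days=("km", "size"))
    out["partial"] = out["n_days"] < 7
    return out


def distance_regression(
    profile: pd.DataFrame, max_week: int = REGRESSION_MAX_WEEK
) -> tuple[float, float, float]:
    """OLS of weekly mean distance on week index over weeks 1..max_week.

    Returns (slope km/week, intercept km, r^2). Later weeks in the profile
    are ignored; fewer than 3 usable weeks is an error.
    """
    use = profile[(profile["week"] >= 1) & (profile["week"] <= max_week)]
    if len(use) < 3:
        raise KeltrackError(f"need >= 3 weekly points within weeks 1..{max_week}")
    res = stats.linregress(use["week"].to_numpy(dtype=float), use["mean_km"].to_numpy())
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def group_weekly_profile(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Group-level weekly means over per-fish profiles (fish present that week)."""
    frames = [p.assign(fish=fid) for fid, p in profiles.items()]
    allp = pd.concat(frames, ignore_index=True)
    return allp.groupby("week", as_index=False).agg(
        mean_km=("mean_km", "mean"), n_fish=("fish", "nunique")
    )


@dataclass
class DepthUseSummary:
    fraction_below: float | None  # fraction of samples deeper than the threshold
    threshold_m: float
    max_depth_m: float | None
    n_samples: int
    empty: bool


def depth_use(
    series: TagSeries,
    threshold_m: float = DEPTH_THRESHOLD_M,
    period: tuple[int, int] | None = None,
    post_migration: bool = False,
) -> DepthUseSummary:
    """Fraction of retained samples deeper than ``threshold_m``.

    ``period`` selects days-since-release [start, end); the
    ``post_migration`` preset keeps samples strictly later than 77 days
    (> 11 weeks) after release.
    """
    if threshold_m <= 0:
        raise KeltrackError("depth threshold must be positive")
    s = series.samples
    day = (
        s["timestamp"].dt.date.map(lambda d: (d - series.deployment.release_date).days)
    ).to_numpy()
    keep = np.ones(len(s), dtype=bool)
    if post_migration:
        keep &= day > POST_MIGRATION_DAYS
    if period is not None:
        keep &= (day >= period[0]) & (day < period[1])
    depths = s.loc[keep, "depth_m"].to_numpy(dtype=float)
    if depths.size == 0:
        return DepthUseSummary(None, threshold_m, None, 0, empty=True)
    return DepthUseSummary(
        fraction_below=float(np.mean(depths > threshold_m)),
        threshold_m=threshold_m,
        max_depth_m=float(depths.max()),
        n_samples=int(depths.size),
        empty=False,
    )


def monthly_thermal_niche(series_by_group: dict[str, list[TagSeries]]) -> pd.DataFrame:
    """Per (group, calendar month): fish and recording counts plus the
    five-number temperature summary over all retained samples.

    Months without samples are simply absent from the output.
    """
    rows = []
    for group, series_list in series_by_group.items():
        frames = []
        for k, series in enumerate(series_list):
            s = series.samples.dropna(subset=["temperature_c"])
            if len(s) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "month": s["timestamp"].dt.month,
                        "temp": s["temperature_c"],
                        "fish": series.deployment.tag_id or str(k),
                    }
                )
            )
        if not frames:
            continue
        allg = pd.concat(frames, ignore_index=True)
        for month, sub in allg.groupby("month"):
            q = np.percentile(sub["temp"], [0, 25, 50, 75, 100])
            rows.append(
                {
                    "group": group,
                    "month": int(month),
                    "n_fish": int(sub["fish"].nunique()),
                    "n_recordings": int(len(sub)),
                    "t_min": q[0],
                    "t_q1": q[1],
                    "t_median": q[2],
                    "t_q3": q[3],
                    "t_max": q[4],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "month", "n_fish", "n_recordings",
            "t_min", "t_q1", "t_median", "t_q3", "t_max",
        ],
    )
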