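"""Hidden Markov model machinery for daily geolocation.

The fish's daily grid cell is the hidden state; the movement kernel is the
transition law; daily likelihood surfaces from light, SST and maximum depth
are the observation model. Forward filtering and backward smoothing run in
linear space with per-day renormalisation (the accumulated normalisers give
the data log-likelihood). Routes are reconstructed as the mean of sampled
tracks (default 1000) drawn from the joint posterior by forward-filter /
backward-sampling, which preserves day-to-day coherence that per-day
marginal draws would lose.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from keltrack.errors import KeltrackError, ShapeError
from keltrack.geo import (
    great_circle_km,
    latlon_to_unit_vectors,
    unit_vectors_to_latlon,
    wrap_lon,
)
from keltrack.observation import (
    LikelihoodParams,
    LikelihoodSurface,
    anchor_surface,
    daily_likelihood,
    daily_observations,
)
from keltrack.spatial_grid import MovementKernel, StateGrid, apply_kernel, build_grid, movement_kernel
from keltrack.tag_io import EnvironmentGrid, TagDeployment, TagSeries


@dataclass
class FilterResult:
    filtered: np.ndarray           # (T+1, K), each row sums to 1
    log_likelihood: float
    degenerate_days: list[int]

    def __iter__(self):
        return iter((self.filtered, self.log_likelihood))


@dataclass
class PosteriorTrack:
    deployment: TagDeployment | None
    grid: StateGrid
    dates: list[dt.date]
    filtered: np.ndarray
    smoothed: np.ndarray
    log_likelihood: float
    degenerate_days: list[int] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def mean_positions(self) -> pd.DataFrame:
        """Per-day posterior-mean position of the smoothed surfaces."""
        vec = latlon_to_unit_vectors(self.grid.lat, self.grid.lon)
        rows = []
        for t, date in enumerate(self.dates):
            m = self.smoothed[t] @ vec
            lat, lon = unit_vectors_to_latlon(m)
            sd_lat = float(np.sqrt(np.sum(self.smoothed[t] * (self.grid.lat - lat) ** 2)))
            dlon = ((self.grid.lon - lon + 180.0) % 360.0) - 180.0
            sd_lon = float(np.sqrt(np.sum(self.smoothed[t] * dlon**2)))
            rows.append((date, float(lat), float(lon), sd_lat, sd_lon))
        return pd.DataFrame(rows, columns=["date", "mean_lat", "mean_lon", "sd_lat", "sd_lon"])


@dataclass
class TrackSampleSet:
    grid: StateGrid
    dates: list[dt.date]
    states: np.ndarray  # (n, T+1) int state indices
    seed: int

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def lat(self) -> np.ndarray:
        return self.grid.lat[self.states]

    @property
    def lon(self) -> np.ndarray:
        return self.grid.lon[self.states]


# ---------------------------------------------------------------------------
# recursions
# ---------------------------------------------------------------------------


def forward_filter(
    anchor0: LikelihoodSurface, kernel: MovementKernel, liks: list[LikelihoodSurface]
) -> FilterResult:
    """Forward recursion: filtered(t) ~ lik(t) * prediction from filtered(t-1).

    ``anchor0`` is the day-0 surface (normally the release anchor);
    ``liks[t-1]`` is day t's likelihood. Degenerate (all-zero) days fall back
    to the prediction alone and are recorded, not fatal. Returns the filtered
    surfaces and the accumulated data log-likelihood.
    """
    K = kernel.n_states
    if anchor0.values.shape != (K,):
        raise ShapeError("anchor surface does not match kernel size")
    c0 = float(anchor0.values.sum())
    if c0 <= 0:
        raise KeltrackError("day-0 anchor surface is all zero")
    T = len(liks)
    filtered = np.empty((T + 1, K))
    filtered[0] = anchor0.values / c0
    loglik = np.log(c0)
    degenerate: list[int] = []
    for t, lik in enumerate(liks, start=1):
        if lik.values.shape != (K,):
            raise ShapeError(f"likelihood surface {t} does not match kernel size")
        pred = apply_kernel(kernel, filtered[t - 1])
        post = pred * lik.values
        c = float(post.sum())
        if lik.degenerate or c <= 0:
            degenerate.append(t)
            post, c = pred, float(pred.sum())
        filtered[t] = post / c
        loglik += np.log(c)
    return FilterResult(filtered, float(loglik), degenerate)


def backward_smooth(filtered: np.ndarray, kernel: MovementKernel) -> np.ndarray:
    """Backward recursion pairing :func:`forward_filter` output.

    smoothed(t)_i = filtered(t)_i * sum_j K_ij smoothed(t+1)_j / pred(t+1)_j
    with pred(t+1) the one-step prediction of filtered(t); 0/0 terms vanish.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2 or filtered.shape[1] != kernel.n_states:
        raise ShapeError("filtered surfaces do not match kernel size")
    T1 = filtered.shape[0]
    smoothed = np.empty_like(filtered)
    smoothed[-1] = filtered[-1]
    M = kernel.matrix
    for t in range(T1 - 2, -1, -1):
        pred = M.T @ filtered[t]
        ratio = np.divide(
            smoothed[t + 1], pred, out=np.zeros_like(pred), where=pred > 0
        )
        s = filtered[t] * (M @ ratio)
        total = s.sum()
        smoothed[t] = s / total if total > 0 else filtered[t]
    return smoothed


def estimate_diffusion(
    anchor0: LikelihoodSurface,
    liks: list[LikelihoodSurface],
    grid: StateGrid,
    bounds: tuple[float, float] = (50.0, 5000.0),
    rel_tol: float = 0.01,
    truncation_sds: float = 4.0,
) -> float:
    """Maximum-likelihood diffusion D (km^2/day) by golden-section search.

    The profile log-likelihood of the forward filter is maximised over
    ``bounds`` to 1% relative tolerance. A flat profile (no movement
    information, e.g. pure-anchor data) triggers a warning and returns the
    interval midpoint.
    """
    lo, hi = bounds
    if not (0 < lo < hi and np.isfinite(hi)):
        raise KeltrackError("bounds must be positive, finite and ordered")

    cache: dict[float, float] = {}

    def ll(D: float) -> float:
        if D not in cache:
            cache[D] = forward_filter(anchor0, movement_kernel(grid, D, truncation_sds), liks).log_likelihood
        return cache[D]

    if abs(ll(lo) - ll(hi)) < 1e-9 and abs(ll(lo) - ll(0.5 * (lo + hi))) < 1e-9:
        warnings.warn("log-likelihood is flat in D; returning interval midpoint")
        return 0.5 * (lo + hi)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    while (b - a) > rel_tol * max(a, 1.0):
        if ll(c) > ll(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = 0.5 * (a + b)
    return float(max([a, b, best, lo, hi], key=ll))


def sample_tracks(
    filtered: np.ndarray,
    kernel: MovementKernel,
    n: int = 1000,
    seed: int = 0,
    grid: StateGrid | None = None,
    dates: list[dt.date] | None = None,
) -> TrackSampleSet:
    """Draw n joint-posterior paths by forward-filter / backward-sampling.

    Day T is drawn from filtered(T); day t from filtered(t) reweighted by the
    kernel column of the day-(t+1) draw. Reproducible given the seed.
    """
    if n <= 0:
        raise KeltrackError("sample count must be positive")
    filtered = np.asarray(filtered, dtype=float)
    T1, K = filtered.shape
    rng = np.random.default_rng(int(seed) % (2**31))
    states = np.empty((n, T1), dtype=np.int64)
    states[:, -1] = rng.choice(K, size=n, p=filtered[-1] / filtered[-1].sum())
    Mcsc = kernel.matrix.tocsc()
    for t in range(T1 - 2, -1, -1):
        nxt = states[:, t + 1]
        for j in np.unique(nxt):
            col = Mcsc.getcol(int(j))
            idx, vals = col.indices, col.data
            w = filtered[t, idx] * vals
            tot = w.sum()
            which = np.flatnonzero(nxt == j)
            if tot <= 0 or idx.size == 0:  # unreachable predecessor: fall back
                p = filtered[t] / filtered[t].sum()
                states[which, t] = rng.choice(K, size=which.size, p=p)
            else:
                states[which, t] = rng.choice(idx, size=which.size, p=w / tot)
    if dates is None:
        dates = [dt.date(2000, 1, 1) + dt.timedelta(days=i) for i in range(T1)]
    if grid is None:
        raise KeltrackError("sample_tracks requires the state grid for coordinates")
    return TrackSampleSet(grid=grid, dates=list(dates), states=states, seed=int(seed))


def mean_track(samples: TrackSampleSet) -> pd.DataFrame:
    """Per-day mean of the sampled paths, computed on unit-sphere vectors.

    The spherical mean is dateline-safe; dispersion is reported as per-day
    standard deviations of latitude and of wrapped longitude offsets.
    """
    lat, lon = samples.lat, samples.lon  # (n, T+1)
    vec = latlon_to_unit_vectors(lat, lon)
    mlat, mlon = unit_vectors_to_latlon(vec.mean(axis=0))
    sd_lat = lat.std(axis=0)
    dlon = ((lon - mlon[None, :] + 180.0) % 360.0) - 180.0
    sd_lon = dlon.std(axis=0)
    return pd.DataFrame(
        {
            "date": samples.dates,
            "mean_lat": np.atleast_1d(mlat),
            "mean_lon": np.atleast_1d(wrap_lon(mlon)),
            "sd_lat": sd_lat,
            "sd_lon": sd_lon,
        }
    )


@dataclass
class TrackComparison:
    daily_km: pd.Series
    mean_km: float
    max_km: float


def compare_tracks(a: pd.DataFrame, b: pd.DataFrame) -> TrackComparison:
    """Per-day and summary great-circle separation of two mean tracks (km)."""
    if list(a["date"]) != list(b["date"]):
        raise ShapeError("tracks cover different dates")
    d = great_circle_km(
        a["mean_lat"].to_numpy(), a["mean_lon"].to_numpy(),
        b["mean_lat"].to_numpy(), b["mean_lon"].to_numpy(),
    )
    daily = pd.Series(d, index=list(a["date"]))
    return TrackComparison(daily, float(d.mean()), float(d.max()))


# ---------------------------------------------------------------------------
# end-to-end geolocation of one tag
# ---------------------------------------------------------------------------


@dataclass
class GeolocationConfig:
    resolution_deg: float = 1.0
    flavour: str = "latlon"
    D_km2_per_day: float = 1000.0
    truncation_sds: float = 4.0
    likelihood: LikelihoodParams = field(default_factory=LikelihoodParams)
    n_tracks: int = 1000
    seed: int = 0


def geolocate(
    series: TagSeries,
    env: EnvironmentGrid,
    config: GeolocationConfig | None = None,
    grid: StateGrid | None = None,
    kernel: MovementKernel | None = None,
) -> tuple[PosteriorTrack, TrackSampleSet, pd.DataFrame]:
    """Run the whole chain for one tag: likelihoods, filter/smooth, sample.

    Returns the posterior track, the sampled track set, and the mean-of-
    samples route (the migration-route estimator). Days without data use a
    uniform likelihood; the release anchors day 0 as a point mass and the
    pop-up position (if known) anchors the final day at Argos-scale sd.
    """
    config = config or GeolocationConfig()
    if grid is None:
        grid = build_grid(env, config.resolution_deg, config.flavour)
    if kernel is None:
        kernel = movement_kernel(grid, config.D_km2_per_day, config.truncation_sds)
    dep = series.deployment
    if dep.popup_date is None:
        raise KeltrackError(f"tag {dep.tag_id}: pop-up date unknown, cannot geolocate")
    n_days = (dep.popup_date - dep.release_date).days
    obs = {o.date: o for o in daily_observations(series, config.likelihood)}

    anchor0 = anchor_surface(grid, dep.release_lat, dep.release_lon, sd_km=0.0)
    liks: list[LikelihoodSurface] = []
    dates = [dep.release_date + dt.timedelta(days=i) for i in range(n_days + 1)]
    for date in dates[1:]:
        o = obs.get(date)
        if o is None:
            liks.append(LikelihoodSurface(date=date, values=np.ones(grid.n_states)))
        else:
            liks.append(daily_likelihood(o, grid, config.likelihood))
    if dep.popup_lat is not None and dep.popup_lon is not None and liks:
        pop = anchor_surface(grid, dep.popup_lat, dep.popup_lon, config.likelihood.popup_sd_km)
        last = liks[-1]
        liks[-1] = LikelihoodSurface(
            date=last.date,
            values=last.values * pop.values,
            components=last.components + ("anchor",),
        )
        if liks[-1].degenerate:  # anchor contradicts data: keep the anchor
            liks[-1] = LikelihoodSurface(date=last.date, values=pop.values,
                                         components=("anchor",))

    res = forward_filter(anchor0, kernel, liks)
    smoothed = backward_smooth(res.filtered, kernel)
    post = PosteriorTrack(
        deployment=dep,
        grid=grid,
        dates=dates,
        filtered=res.filtered,
        smoothed=smoothed,
        log_likelihood=res.log_likelihood,
        degenerate_days=res.degenerate_days,
    )
    samples = sample_tracks(
        res.filtered, kernel, n=config.n_tracks, seed=config.seed, grid=grid, dates=dates
    )
    return post, samples, mean_track(samples)
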