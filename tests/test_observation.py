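import datetime as dt

import numpy as np
import pandas as pd
import pytest

from keltrack import solar
from keltrack.observation import (
    DailyObservation,
    LikelihoodParams,
    anchor_surface,
    daily_likelihood,
    daily_observations,
    light_position,
)
from keltrack.spatial_grid import build_grid
from keltrack.synthetic import MovementParams, TagParams, simulate_tag_series, simulate_track
from keltrack.tag_io import TagDeployment, TagSeries
from conftest import ocean_config


def utc(y, mo, d, h, mi=0):
    return dt.datetime(y, mo, d, h, mi, tzinfo=dt.timezone.utc)


def series_from_rows(rows, release=dt.date(2010, 5, 1)):
    dep = TagDeployment(
        tag_id="t", population="p", release_date=release, release_lat=55.0, release_lon=-5.0
    )
    samples = pd.DataFrame(rows, columns=["timestamp", "depth_m", "temperature_c"])
    samples["timestamp"] = pd.to_datetime(samples["timestamp"], utc=True)
    return TagSeries(deployment=dep, samples=samples)


class TestDailyObservations:
    def test_max_depth_and_shallow_sst(self):
        rows = [
            (utc(2010, 5, 1, 0), 1.0, 10.0),
            (utc(2010, 5, 1, 1), 3.0, 10.2),
            (utc(2010, 5, 1, 2), 25.0, 8.0),
        ]
        obs = daily_observations(series_from_rows(rows))
        assert len(obs) == 1
        assert obs[0].max_depth_m == 25.0
        assert obs[0].sst_c == pytest.approx(10.1)

    def test_all_deep_day_has_no_sst(self):
        rows = [(utc(2010, 5, 1, h), 30.0, 5.0) for h in range(3)]
        obs = daily_observations(series_from_rows(rows))
        assert obs[0].sst_c is None
        assert obs[0].max_depth_m == 30.0

    def test_days_without_samples_absent(self):
        rows = [
            (utc(2010, 5, 1, 0), 1.0, 10.0),
            (utc(2010, 5, 3, 0), 1.0, 10.0),
        ]
        obs = daily_observations(series_from_rows(rows))
        assert [o.date for o in obs] == [dt.date(2010, 5, 1), dt.date(2010, 5, 3)]

    def test_empty_series_gives_empty_sequence(self):
        assert daily_observations(series_from_rows([])) == []


class TestLightPosition:
    def test_symmetric_twilights_at_equinox_give_lon_zero(self):
        lon, lat, usable = light_position(
            utc(2010, 3, 20, 6), utc(2010, 3, 20, 18), dt.date(2010, 3, 20)
        )
        assert lon == pytest.approx(0.0)
        assert usable is False  # 12 h day at the equinox: latitude degenerate

    def test_one_hour_noon_offset_is_15_degrees_east(self):
        lon, _, _ = light_position(
            utc(2010, 6, 1, 5), utc(2010, 6, 1, 17), dt.date(2010, 6, 1)
        )
        assert lon == pytest.approx(15.0)

    @pytest.mark.parametrize("lat_true,lon_true", [(60.0, -10.0), (45.0, 20.0), (65.0, 0.0)])
    def test_inverts_forward_solar_model(self, lat_true, lon_true):
        date = dt.date(2010, 6, 1)
        tw = solar.twilight_times_utc(date, lat_true, lon_true)
        lon, lat, usable = light_position(tw[0], tw[1], date)
        assert lon == pytest.approx(lon_true, abs=1e-6)
        assert lat == pytest.approx(lat_true, abs=1e-6)
        assert usable

    def test_southern_hemisphere_short_day_recovered(self):
        date = dt.date(2010, 6, 1)  # austral winter: day < 12 h
        tw = solar.twilight_times_utc(date, -40.0, 10.0)
        _, lat, _ = light_position(tw[0], tw[1], date)
        assert lat == pytest.approx(-40.0, abs=1e-6)

    def test_polar_day_has_no_twilight(self):
        assert solar.twilight_times_utc(dt.date(2010, 6, 21), 80.0, 0.0) is None


class TestDailyLikelihood:
    def test_depth_only_is_bathymetry_indicator(self, coastal_env):
        grid = build_grid(coastal_env, 1.0)
        obs = DailyObservation(date=dt.date(2010, 7, 1), max_depth_m=500.0)
        surf = daily_likelihood(obs, grid)
        feasible = grid.bathymetry + 10.0 >= 500.0
        assert np.array_equal(surf.values > 0, feasible)
        assert len(np.unique(surf.values[surf.values > 0])) == 1

    def test_sst_only_peaks_where_field_matches(self, ocean_env):
        grid = build_grid(ocean_env, 1.0)
        month = 7
        target = float(grid.sst(month)[10])
        obs = DailyObservation(date=dt.date(2010, 7, 1), sst_c=target)
        surf = daily_likelihood(obs, grid)
        best = np.flatnonzero(surf.values == surf.values.max())
        match = np.flatnonzero(
            np.abs(grid.sst(month) - target)
            == np.abs(grid.sst(month) - target).min()
        )
        assert set(best) == set(match)

    def test_three_component_product_matches_hand_evaluation(self):
        # 1x3 ocean strip with distinct SSTs and bathymetry; every component
        # multiplied by hand for comparison
        from test_spatial_grid import toy_env

        env = toy_env(nlat=1, nlon=3, lat0=54.5)
        env.sst[:] = np.array([6.0, 8.0, 10.0])[None, None, :]
        env.bathymetry[0] = [100.0, 400.0, 800.0]
        grid = build_grid(env, 1.0)
        params = LikelihoodParams(sigma_lon_deg=1.0, sigma_lat_deg=2.0, sigma_sst_c=1.0)
        obs = DailyObservation(
            date=dt.date(2010, 7, 15), max_depth_m=350.0, sst_c=8.5,
            light_lon_deg=-4.5, light_lat_deg=55.0, lat_usable=True,
        )
        surf = daily_likelihood(obs, grid, params)
        order = np.argsort(grid.lon)
        hand = []
        for j in order:
            g_lon = np.exp(-0.5 * ((grid.lon[j] + 4.5) / 1.0) ** 2)
            g_lat = np.exp(-0.5 * ((grid.lat[j] - 55.0) / 2.0) ** 2)
            g_sst = np.exp(-0.5 * ((grid.sst(7)[j] - 8.5) / 1.0) ** 2)
            ind = 1.0 if grid.bathymetry[j] + 10.0 >= 350.0 else 0.0
            hand.append(g_lon * g_lat * g_sst * ind)
        assert np.allclose(surf.values[order], hand, rtol=1e-12)
        assert surf.values[order][0] == 0.0  # 100 m sea floor excludes 350 m dive

    def test_missing_components_give_uniform_surface(self, ocean_env):
        grid = build_grid(ocean_env, 1.0)
        obs = DailyObservation(date=dt.date(2010, 7, 1))
        surf = daily_likelihood(obs, grid)
        assert np.allclose(surf.values, 1.0)
        assert not surf.degenerate

    def test_impossible_depth_flags_degenerate(self, ocean_env):
        grid = build_grid(ocean_env, 1.0)
        obs = DailyObservation(date=dt.date(2010, 7, 1), max_depth_m=99999.0)
        assert daily_likelihood(obs, grid).degenerate

    def test_true_cell_in_argmax_for_noise_free_observations(self, ocean_env):
        # release off any cell boundary so "the true cell" is unambiguous
        cfg = ocean_config(seed=21, release_lat=52.3, release_lon=-7.8)
        cfg.tag = TagParams(
            sst_noise_sd_c=0.0, twilight_skew_sd_min=0.0, twilight_clock_sd_min=0.0,
            dropout=0.0, deployment_days=25,
        )
        cfg.movement = MovementParams(speed_km_per_day=15.0, target_lat=58.0, target_lon=-2.0)
        track = simulate_track(ocean_env, cfg)
        series = simulate_tag_series(track, ocean_env, cfg)
        grid = build_grid(ocean_env, 1.0)
        by_date = {d: (la, lo) for d, la, lo in
                   track.positions[["date", "lat", "lon"]].itertuples(index=False)}
        checked = 0
        for obs in daily_observations(series):
            surf = daily_likelihood(obs, grid)
            if surf.degenerate:
                continue
            la, lo = by_date[obs.date]
            true_state = grid.nearest_state(la, lo)
            best = surf.values.max()
            assert surf.values[true_state] >= best * (1 - 1e-9)
            checked += 1
        assert checked >= 20


class TestAnchorSurface:
    def test_release_anchor_is_point_mass_at_nearest_ocean_cell(self, coastal_env):
        grid = build_grid(coastal_env, 1.0)
        surf = anchor_surface(grid, 60.2, 5.1, sd_km=0.0)
        assert (surf.values > 0).sum() == 1
        assert surf.values.sum() == 1.0

    def test_popup_anchor_mass_concentrated_nearby(self, ocean_env):
        grid = build_grid(ocean_env, 1.0)
        surf = anchor_surface(grid, 55.0, -5.0, sd_km=10.0)
        p = surf.values / surf.values.sum()
        from keltrack.geo import great_circle_km

        d = great_circle_km(55.0, -5.0, grid.lat, grid.lon)
        assert p[d < 160.0].sum() > 0.99

    def test_land_location_shifts_to_nearest_ocean(self, coastal_env):
        grid = build_grid(coastal_env, 1.0)
        # pick a land cell adjacent to the coast
        i, j = np.argwhere(coastal_env.land_mask)[0]
        lat, lon = coastal_env.lat[i], coastal_env.lon[j]
        surf = anchor_surface(grid, float(lat), float(lon), sd_km=0.0)
        k = int(np.flatnonzero(surf.values)[0])
        assert coastal_env.is_ocean(grid.lat[k], grid.lon[k])
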