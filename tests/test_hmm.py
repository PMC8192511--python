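import datetime as dt

import numpy as np
import pandas as pd
import pytest

from keltrack.errors import KeltrackError, ShapeError
from keltrack.hmm import (
    backward_smooth,
    compare_tracks,
    estimate_diffusion,
    forward_filter,
    mean_track,
    sample_tracks,
)
from keltrack.observation import LikelihoodSurface, anchor_surface
from keltrack.spatial_grid import build_grid, movement_kernel
from keltrack.hmm import TrackSampleSet
from conftest import dense_kernel, enumerate_marginals, random_hmm_instance


def surf(values):
    return LikelihoodSurface(date=None, values=np.asarray(values, dtype=float))


class TestForwardFilter:
    def test_two_cell_hand_example(self):
        kern = dense_kernel([[0.7, 0.3], [0.3, 0.7]])
        res = forward_filter(surf([1.0, 0.0]), kern, [surf([1.0, 1.0])])
        assert np.allclose(res.filtered[1], [0.7, 0.3])

    def test_uniform_everything_stays_uniform(self):
        kern = dense_kernel([[0.6, 0.4], [0.4, 0.6]])  # doubly stochastic
        res = forward_filter(surf([0.5, 0.5]), kern, [surf([1, 1])] * 4)
        assert np.allclose(res.filtered, 0.5)

    def test_identity_kernel_point_mass_absorbs(self):
        kern = dense_kernel(np.eye(3))
        liks = [surf([0.2, 5.0, 3.0]), surf([1.0, 0.5, 9.0])]
        res = forward_filter(surf([0.0, 1.0, 0.0]), kern, liks)
        assert np.allclose(res.filtered, [[0, 1, 0], [0, 1, 0], [0, 1, 0]])

    def test_all_zero_anchor_rejected(self):
        kern = dense_kernel(np.eye(2))
        with pytest.raises(KeltrackError):
            forward_filter(surf([0.0, 0.0]), kern, [])

    def test_degenerate_day_falls_back_to_prediction(self):
        kern = dense_kernel([[0.7, 0.3], [0.3, 0.7]])
        res = forward_filter(surf([1.0, 0.0]), kern, [surf([0.0, 0.0])])
        assert res.degenerate_days == [1]
        assert np.allclose(res.filtered[1], [0.7, 0.3])

    def test_log_likelihood_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(5)
        anchor, kern, liks = random_hmm_instance(rng, max_cells=8, max_days=4)
        res = forward_filter(surf(anchor), kern, [surf(l) for l in liks])
        perm = rng.permutation(kern.matrix.shape[0])
        M = kern.matrix.toarray()[np.ix_(perm, perm)]
        res_p = forward_filter(
            surf(anchor[perm]), dense_kernel(M), [surf(l[perm]) for l in liks]
        )
        assert res_p.log_likelihood == pytest.approx(res.log_likelihood, rel=1e-12)


class TestBackwardSmooth:
    def test_point_anchor_day0_stays_fixed(self):
        kern = dense_kernel([[0.7, 0.3], [0.3, 0.7]])
        res = forward_filter(surf([1.0, 0.0]), kern, [surf([1.0, 1.0])])
        smoothed = backward_smooth(res.filtered, kern)
        assert np.allclose(smoothed[0], [1.0, 0.0])

    def test_single_day_smoothed_equals_filtered(self):
        kern = dense_kernel(np.eye(2))
        res = forward_filter(surf([0.3, 0.7]), kern, [])
        smoothed = backward_smooth(res.filtered, kern)
        assert np.array_equal(smoothed, res.filtered)

    def test_final_smoothed_equals_final_filtered(self):
        rng = np.random.default_rng(2)
        anchor, kern, liks = random_hmm_instance(rng, max_cells=10, max_days=5)
        res = forward_filter(surf(anchor), kern, [surf(l) for l in liks])
        smoothed = backward_smooth(res.filtered, kern)
        assert np.allclose(smoothed[-1], res.filtered[-1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        anchor, kern, liks = random_hmm_instance(rng, max_paths=20_000)
        res = forward_filter(surf(anchor), kern, [surf(l) for l in liks])
        smoothed = backward_smooth(res.filtered, kern)
        oracle = enumerate_marginals(anchor, kern, liks)
        assert np.max(np.abs(smoothed - oracle)) < 1e-10

    def test_probability_conserved_every_day(self):
        rng = np.random.default_rng(9)
        anchor, kern, liks = random_hmm_instance(rng)
        res = forward_filter(surf(anchor), kern, [surf(l) for l in liks])
        smoothed = backward_smooth(res.filtered, kern)
        assert np.allclose(res.filtered.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(smoothed.sum(axis=1), 1.0, atol=1e-9)


class TestEstimateDiffusion:
    def _grid(self, ocean_env):
        return build_grid(ocean_env, 1.0)

    def test_recovers_generating_diffusion(self, ocean_env):
        # simulate a chain straight from the D=1000 kernel, observe each day
        # with a tight positional likelihood, and re-estimate D
        grid = self._grid(ocean_env)
        D_true = 1000.0
        kern = movement_kernel(grid, D_true)
        rng = np.random.default_rng(77)
        state = grid.nearest_state(55.0, -5.0)
        M = kern.matrix
        states = [state]
        for _ in range(60):
            row = M.getrow(states[-1])
            states.append(int(rng.choice(row.indices, p=row.data / row.data.sum())))
        liks = [
            anchor_surface(grid, float(grid.lat[s]), float(grid.lon[s]), sd_km=30.0)
            for s in states[1:]
        ]
        anchor0 = anchor_surface(grid, float(grid.lat[states[0]]), float(grid.lon[states[0]]), 0.0)
        D_hat = estimate_diffusion(anchor0, liks, grid, bounds=(200.0, 5000.0))
        assert 500.0 <= D_hat <= 2000.0

    def test_flat_likelihood_warns_and_returns_midpoint(self, ocean_env):
        grid = self._grid(ocean_env)
        anchor0 = anchor_surface(grid, 55.0, -5.0, sd_km=0.0)
        uniform = [LikelihoodSurface(date=None, values=np.ones(grid.n_states))]
        with pytest.warns(UserWarning, match="flat"):
            D = estimate_diffusion(anchor0, uniform, grid, bounds=(100.0, 300.0))
        assert D == pytest.approx(200.0)

    def test_returned_D_beats_both_bounds(self, ocean_env):
        grid = self._grid(ocean_env)
        rng = np.random.default_rng(3)
        anchor0 = anchor_surface(grid, 55.0, -5.0, sd_km=0.0)
        liks = [
            anchor_surface(grid, 55.0 + 0.5 * t, -5.0, sd_km=50.0) for t in range(1, 8)
        ]
        bounds = (100.0, 4000.0)
        D_hat = estimate_diffusion(anchor0, liks, grid, bounds=bounds)

        def ll(D):
            return forward_filter(anchor0, movement_kernel(grid, D), liks).log_likelihood

        assert ll(D_hat) >= ll(bounds[0]) - 1e-9
        assert ll(D_hat) >= ll(bounds[1]) - 1e-9


class TestSampleTracks:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        K = 9
        M = rng.random((K, K)) + 0.05
        M /= M.sum(axis=1, keepdims=True)
        kern = dense_kernel(M)
        anchor = np.zeros(K)
        anchor[4] = 1.0
        liks = [surf(rng.random(K) + 0.05) for _ in range(5)]
        return kern, anchor, liks

    def _fake_grid(self, K):
        class _G:
            lat = np.linspace(50, 58, K)
            lon = np.linspace(-8, 0, K)

        return _G()

    def test_point_mass_posterior_gives_identical_paths(self):
        kern = dense_kernel(np.eye(3))
        res = forward_filter(surf([0, 1, 0]), kern, [surf([0, 1, 0])] * 3)
        samples = sample_tracks(res.filtered, kern, n=50, seed=1, grid=self._fake_grid(3))
        assert np.all(samples.states == 1)

    def test_empirical_marginals_match_smoothed(self):
        # day-marginals of 10,000 joint-posterior samples vs the smoothed
        # distributions on a 9-cell toy: total variation <= 0.05
        kern, anchor, liks = self._toy(4)
        res = forward_filter(surf(anchor), kern, liks)
        smoothed = backward_smooth(res.filtered, kern)
        samples = sample_tracks(res.filtered, kern, n=10_000, seed=2, grid=self._fake_grid(9))
        for t in range(smoothed.shape[0]):
            emp = np.bincount(samples.states[:, t], minlength=9) / samples.n_samples
            tv = 0.5 * np.abs(emp - smoothed[t]).sum()
            assert tv <= 0.05

    def test_same_seed_identical_samples(self):
        kern, anchor, liks = self._toy(6)
        res = forward_filter(surf(anchor), kern, liks)
        a = sample_tracks(res.filtered, kern, n=100, seed=9, grid=self._fake_grid(9))
        b = sample_tracks(res.filtered, kern, n=100, seed=9, grid=self._fake_grid(9))
        assert np.array_equal(a.states, b.states)

    def test_nonpositive_count_rejected(self):
        kern, anchor, liks = self._toy()
        res = forward_filter(surf(anchor), kern, liks)
        with pytest.raises(KeltrackError):
            sample_tracks(res.filtered, kern, n=0, grid=self._fake_grid(9))


class TestMeanTrack:
    def _sample_set(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        K = lat.size

        class _G:
            pass

        g = _G()
        g.lat = lat
        g.lon = np.asarray(lon, dtype=float)
        states = np.tile(np.arange(K), (1, 1))
        return g, states

    def test_identical_samples_give_that_path(self):
        g, _ = self._sample_set([55.0, 56.0], [-5.0, -4.0])
        states = np.zeros((7, 2), dtype=int)
        states[:, 1] = 1
        ss = TrackSampleSet(grid=g, dates=[dt.date(2010, 5, 1), dt.date(2010, 5, 2)],
                            states=states, seed=0)
        mt = mean_track(ss)
        assert np.allclose(mt["mean_lat"], [55.0, 56.0])
        assert np.allclose(mt["mean_lon"], [-5.0, -4.0])
        assert np.allclose(mt["sd_lat"], 0.0)

    def test_dateline_mean_is_180_not_0(self):
        g, _ = self._sample_set([60.0, 60.0], [179.0, -179.0])
        states = np.array([[0], [1]])
        ss = TrackSampleSet(grid=g, dates=[dt.date(2010, 5, 1)], states=states, seed=0)
        mt = mean_track(ss)
        assert abs(abs(mt["mean_lon"].iloc[0]) - 180.0) < 1e-9

    def test_sample_mean_approaches_exact_posterior_mean(self):
        from keltrack.geo import great_circle_km, latlon_to_unit_vectors, unit_vectors_to_latlon

        rng = np.random.default_rng(12)
        K = 9
        M = rng.random((K, K)) + 0.05
        M /= M.sum(axis=1, keepdims=True)
        kern = dense_kernel(M)
        anchor = rng.random(K)
        liks = [surf(rng.random(K) + 0.05) for _ in range(4)]
        res = forward_filter(surf(anchor), kern, liks)
        smoothed = backward_smooth(res.filtered, kern)
        g = type("G", (), {})()
        g.lat = np.linspace(50, 58, K)
        g.lon = np.linspace(-8, 0, K)
        n = 20_000
        samples = sample_tracks(res.filtered, kern, n=n, seed=3, grid=g)
        mt = mean_track(samples)
        vec = latlon_to_unit_vectors(g.lat, g.lon)
        for t in range(smoothed.shape[0]):
            exact_lat, exact_lon = unit_vectors_to_latlon(smoothed[t] @ vec)
            d = great_circle_km(mt["mean_lat"][t], mt["mean_lon"][t], exact_lat, exact_lon)
            # ~3 MC sds of the per-day mean over a <= 900 km support
            assert d < 3.0 * 900.0 / np.sqrt(n)


class TestCompareTracks:
    def _track(self, lats, lons):
        dates = [dt.date(2010, 5, 1) + dt.timedelta(days=i) for i in range(len(lats))]
        return pd.DataFrame(
            {"date": dates, "mean_lat": lats, "mean_lon": lons,
             "sd_lat": 0.0, "sd_lon": 0.0}
        )

    def test_identical_tracks_zero_separation(self):
        t = self._track([55, 56, 57], [-5, -5, -5])
        cmp = compare_tracks(t, t)
        assert cmp.mean_km == 0.0 and cmp.max_km == 0.0

    def test_one_degree_latitude_offset(self):
        a = self._track([55, 56], [-5, -5])
        b = self._track([56, 57], [-5, -5])
        cmp = compare_tracks(a, b)
        assert cmp.mean_km == pytest.approx(111.19, abs=0.01)

    def test_date_mismatch_rejected(self):
        a = self._track([55], [-5])
        b = self._track([55, 56], [-5, -5])
        with pytest.raises(ShapeError):
            compare_tracks(a, b)
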