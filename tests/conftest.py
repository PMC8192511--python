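import datetime as dt

import numpy as np
import pytest
from scipy import sparse

from keltrack.spatial_grid import MovementKernel
from keltrack.synthetic import (
    EnvironmentParams,
    SimulationConfig,
    generate_environment,
    simulate_tag_series,
    simulate_track,
)


def ocean_config(**kw) -> SimulationConfig:
    """Small all-ocean, noise-free environment for focused tests."""
    env = EnvironmentParams(
        lat_min=50.0, lat_max=60.0, lon_min=-10.0, lon_max=0.0,
        noise_sd_c=0.0, coast_lon_deg=None,
    )
    kw.setdefault("release_lat", 52.0)
    kw.setdefault("release_lon", -8.0)
    return SimulationConfig(environment=env, **kw)


@pytest.fixture(scope="session")
def ocean_env():
    return generate_environment(ocean_config(seed=1))


@pytest.fixture(scope="session")
def coastal_env():
    cfg = SimulationConfig(seed=1)
    return generate_environment(cfg)


@pytest.fixture(scope="session")
def sim_deployment(coastal_env):
    """One default-condition simulated fish shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    track = simulate_track(coastal_env, cfg)
    series = simulate_tag_series(track, coastal_env, cfg)
    return cfg, track, series


def dense_kernel(matrix) -> MovementKernel:
    """Wrap a hand-built row-stochastic matrix as a movement kernel."""
    m = np.asarray(matrix, dtype=float)
    return MovementKernel(sparse.csr_matrix(m), D_km2_per_day=float("nan"), truncation_km=0.0)


def random_hmm_instance(rng, max_cells=25, max_days=6, max_paths=100_000):
    """Random anchor/kernel/likelihood instance small enough to enumerate."""
    while True:
        K = int(rng.integers(2, max_cells + 1))
        T = int(rng.integers(1, max_days))  # days beyond day 0
        if K ** (T + 1) <= max_paths:
            break
    M = rng.random((K, K)) + 1e-3
    M /= M.sum(axis=1, keepdims=True)
    anchor = rng.random(K) + 1e-3
    liks = [rng.random(K) + 1e-3 for _ in range(T)]
    return anchor, dense_kernel(M), liks


def enumerate_marginals(anchor, kernel, liks):
    """Brute-force smoothed marginals: literal sum over every complete path.

    Enumerates all K**(T+1) paths (vectorised), weights each by
    anchor * transitions * likelihoods, and bins the weights per (day, cell).
    Independent of the forward-backward recursion it checks.
    """
    M = kernel.matrix.toarray()
    K = M.shape[0]
    T = len(liks)
    paths = np.unravel_index(np.arange(K ** (T + 1)), (K,) * (T + 1))
    w = anchor[paths[0]].astype(float)
    for t in range(1, T + 1):
        w = w * M[paths[t - 1], paths[t]] * liks[t - 1][paths[t]]
    marg = np.stack([np.bincount(paths[t], weights=w, minlength=K) for t in range(T + 1)])
    return marg / w.sum()
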