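"""Discretised ocean state space and the daily movement kernel.

Two flavours of discretisation are supported, mirroring the two geolocation
model variants being compared: ``latlon`` (one state per ocean lat/lon cell)
and ``distance`` (cell centers ~equidistant in km, longitude spacing widened
by 1/cos(lat)). Movement over one day is a truncated Gaussian diffusion
kernel; land never holds probability because land cells are simply not
states, and mass that would diffuse ashore is reflected back by row
renormalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from keltrack.errors import ConfigError, GridError, ShapeError
from keltrack.geo import EARTH_RADIUS_KM, great_circle_km, latlon_to_unit_vectors
from keltrack.tag_io import EnvironmentGrid

KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class StateGrid:
    """Ordered ocean cells forming the HMM state space."""

    lat: np.ndarray        # (K,) cell-center latitudes
    lon: np.ndarray        # (K,) cell-center longitudes
    area_km2: np.ndarray   # (K,) nominal cell areas
    env_i: np.ndarray      # (K,) row index into the environment grid
    env_j: np.ndarray      # (K,) column index into the environment grid
    resolution_deg: float
    flavour: str
    env: EnvironmentGrid

    @property
    def n_states(self) -> int:
        return self.lat.size

    def nearest_state(self, lat: float, lon: float) -> int:
        d = great_circle_km(lat, lon, self.lat, self.lon)
        return int(np.argmin(d))

    def sst(self, month: int) -> np.ndarray:
        """Environment SST at every state for a calendar month (1..12)."""
        return self.env.sst[month - 1, self.env_i, self.env_j]

    @property
    def bathymetry(self) -> np.ndarray:
        return self.env.bathymetry[self.env_i, self.env_j]


@dataclass
class MovementKernel:
    """Row-stochastic daily transition weights between ocean states."""

    matrix: sparse.csr_matrix
    D_km2_per_day: float
    truncation_km: float

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def build_grid(env: EnvironmentGrid, resolution_deg: float, flavour: str = "latlon") -> StateGrid:
    """Discretise the ocean part of ``env`` into HMM states.

    ``resolution_deg`` must be an integer multiple of the environment
    resolution; fields are looked up at the environment cell nearest each
    state center, and a state exists only where that cell is ocean.
    """
    if flavour not in ("latlon", "distance"):
        raise ConfigError(f"unknown grid flavour {flavour!r}")
    factor = resolution_deg / env.resolution_deg
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ConfigError(
            f"resolution {resolution_deg} is not an integer coarsening of "
            f"the {env.resolution_deg} deg environment"
        )
    factor = int(round(factor))
    lat_c = env.lat[factor // 2 :: factor]
    lon_c = env.lon[factor // 2 :: factor]

    lats, lons, areas, eis, ejs = [], [], [], [], []
    for la in lat_c:
        coslat = math.cos(math.radians(la))
        if flavour == "distance":
            stride = max(1, int(round(1.0 / max(coslat, 1e-6))))
        else:
            stride = 1
        for lo in lon_c[::stride]:
            i = int(np.argmin(np.abs(env.lat - la)))
            j = int(np.argmin(np.abs(env.lon - lo)))
            if env.land_mask[i, j]:
                continue
            lats.append(la)
            lons.append(lo)
            areas.append((KM_PER_DEG * resolution_deg) ** 2 * coslat * stride)
            eis.append(i)
            ejs.append(j)
    if not lats:
        raise GridError("no ocean cells in domain (all land)")
    return StateGrid(
        lat=np.asarray(lats),
        lon=np.asarray(lons),
        area_km2=np.asarray(areas),
        env_i=np.asarray(eis, dtype=int),
        env_j=np.asarray(ejs, dtype=int),
        resolution_deg=float(resolution_deg),
        flavour=flavour,
        env=env,
    )


def movement_kernel(
    grid: StateGrid, D_km2_per_day: float, truncation_sds: float = 4.0
) -> MovementKernel:
    """Truncated Gaussian diffusion kernel for one daily step.

    weight(src -> dst) is proportional to exp(-d^2 / (4 D)) with d the
    great-circle distance in km, zero beyond ``truncation_sds`` per-axis
    standard deviations (sd = sqrt(2 D)), then renormalised over the ocean
    destinations of each source (reflecting boundary at coasts).
    """
    if D_km2_per_day < 0:
        raise ConfigError("diffusion D must be >= 0")
    K = grid.n_states
    if D_km2_per_day == 0:
        return MovementKernel(sparse.identity(K, format="csr"), 0.0, 0.0)
    sd = math.sqrt(2.0 * D_km2_per_day)
    radius_km = truncation_sds * sd
    vec = latlon_to_unit_vectors(grid.lat, grid.lon) * EARTH_RADIUS_KM
    # chord length bounding the great-circle truncation radius
    chord = 2.0 * EARTH_RADIUS_KM * math.sin(min(radius_km / (2.0 * EARTH_RADIUS_KM), math.pi / 2))
    tree = cKDTree(vec)
    pairs = tree.query_pairs(chord, output_type="ndarray")
    src = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(K)])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(K)])
    d = great_circle_km(grid.lat[src], grid.lon[src], grid.lat[dst], grid.lon[dst])
    keep = d <= radius_km
    src, dst, d = src[keep], dst[keep], d[keep]
    w = np.exp(-(d**2) / (4.0 * D_km2_per_day)) * grid.area_km2[dst]
    mat = sparse.csr_matrix((w, (src, dst)), shape=(K, K))
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / rowsum)
    return MovementKernel((inv @ mat).tocsr(), float(D_km2_per_day), float(radius_km))


def apply_kernel(kernel: MovementKernel, p: np.ndarray) -> np.ndarray:
    """One prediction step: out[dst] = sum_src p[src] * weight(src -> dst)."""
    p = np.asarray(p, dtype=float)
    if p.shape != (kernel.n_states,):
        raise ShapeError(f"surface shape {p.shape} does not match kernel {kernel.n_states}")
    return kernel.matrix.T @ p
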