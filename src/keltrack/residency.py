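"""Residency distributions and Bhattacharyya overlap between populations.

A residency distribution (RD) is the time-integrated, normalized posterior
probability surface of a fish: the per-day smoothed surfaces averaged over
the track. Population RDs combine the per-fish RDs of all fish whose ocean
migration exceeds a day threshold (default: strictly more than 10 days),
with equal weight per fish by default so long tracks do not dominate.
Overlap between two RDs is Bhattacharyya's affinity
``BA = sum_cells sqrt(p * q)`` — 1 for identical distributions, 0 for
disjoint ones — interpreted as proportion overlap in space use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from keltrack.errors import KeltrackError, ShapeError, ValidationError
from keltrack.hmm import PosteriorTrack
from keltrack.spatial_grid import StateGrid

_NORM_TOL = 1e-6


@dataclass
class ResidencyDistribution:
    grid: StateGrid
    values: np.ndarray           # (K,) normalized
    source: str = ""
    n_fish: int = 1
    n_fish_days: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (self.grid.n_states,):
            raise ShapeError("RD values do not match grid size")
        if np.any(self.values < 0):
            raise ValidationError("RD has negative cells")
        if abs(float(self.values.sum()) - 1.0) > _NORM_TOL:
            raise ValidationError(f"RD not normalized (sum={self.values.sum()!r})")

    def to_dataarray(self) -> xr.DataArray:
        """Rasterize onto the environment lat/lon lattice (land cells 0)."""
        env = self.grid.env
        field = np.zeros((env.lat.size, env.lon.size))
        np.add.at(field, (self.grid.env_i, self.grid.env_j), self.values)
        return xr.DataArray(
            field, dims=("lat", "lon"), coords={"lat": env.lat, "lon": env.lon}, name="rd"
        )


@dataclass
class OverlapMatrix:
    labels: list[str]
    affinity: np.ndarray  # symmetric, diag 1, entries in [0, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.affinity, index=self.labels, columns=self.labels)


def residency_distribution(track: PosteriorTrack) -> ResidencyDistribution:
    """Per-fish RD: mean of the daily smoothed surfaces."""
    if track.n_days < 1:
        raise KeltrackError("track has no days")
    values = track.smoothed.mean(axis=0)
    return ResidencyDistribution(
        grid=track.grid,
        values=values / values.sum(),
        source=track.deployment.tag_id if track.deployment else "",
        n_fish=1,
        n_fish_days=track.n_days,
    )


def combine_rds(
    rds: list[ResidencyDistribution],
    track_days: list[int],
    min_days: int = 10,
    label: str = "",
    weighting: str = "fish",
) -> ResidencyDistribution:
    """Population RD over fish with migrations strictly exceeding ``min_days``.

    ``weighting='fish'`` (default) averages per-fish RDs with equal weight;
    ``weighting='days'`` pools fish-days instead.
    """
    if len(rds) != len(track_days):
        raise ShapeError("rds and track_days length mismatch")
    if weighting not in ("fish", "days"):
        raise KeltrackError(f"unknown weighting {weighting!r}")
    keep = [(rd, d) for rd, d in zip(rds, track_days) if d > min_days]
    if not keep:
        raise KeltrackError(f"no fish with migrations exceeding {min_days} days")
    grid = keep[0][0].grid
    for rd, _ in keep:
        if rd.grid.n_states != grid.n_states:
            raise ShapeError("RDs live on different grids")
    if weighting == "fish":
        combined = np.mean([rd.values for rd, _ in keep], axis=0)
    else:
        combined = np.sum([rd.values * d for rd, d in keep], axis=0)
    combined = combined / combined.sum()
    return ResidencyDistribution(
        grid=grid,
        values=combined,
        source=label,
        n_fish=len(keep),
        n_fish_days=int(sum(d for _, d in keep)),
    )


def bhattacharyya(p: ResidencyDistribution, q: ResidencyDistribution) -> float:
    """Bhattacharyya's affinity between two RDs on the same grid."""
    if p.grid.n_states != q.grid.n_states:
        raise ShapeError("RDs live on different grids")
    p.validate()
    q.validate()
    return float(np.clip(np.sum(np.sqrt(p.values * q.values)), 0.0, 1.0))


def overlap_matrix(populations: list[tuple[str, ResidencyDistribution]]) -> OverlapMatrix:
    """All pairwise Bhattacharyya affinities between labelled population RDs."""
    labels = [lbl for lbl, _ in populations]
    if len(set(labels)) != len(labels):
        raise KeltrackError("duplicate population labels")
    if len(labels) < 2:
        raise KeltrackError("need at least 2 populations")
    n = len(labels)
    aff = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aff[i, j] = aff[j, i] = bhattacharyya(populations[i][1], populations[j][1])
    return OverlapMatrix(labels=labels, affinity=aff)


def contour_mask(rd: ResidencyDistribution, mass: float = 0.95) -> np.ndarray:
    """Boolean mask of the smallest cell set holding ``mass`` cumulative probability.

    Display aid for home-range style outlines; overlap is always computed on
    the full distribution, not on these contours.
    """
    order = np.argsort(rd.values)[::-1]
    cum = np.cumsum(rd.values[order])
    k = int(np.searchsorted(cum, mass)) + 1
    mask = np.zeros(rd.values.size, dtype=bool)
    mask[order[:k]] = True
    return mask
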