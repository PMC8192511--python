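"""Read/write tag series, environment grids and derived products.

Formats are deliberately plain:

* tag series — ``<stem>.csv`` with columns ``timestamp,depth_m,temperature_c``
  (ISO-8601 UTC timestamps, "." decimal, empty string = missing), a companion
  ``<stem>.meta.json`` holding the deployment metadata, and an optional
  ``<stem>.twl.csv`` with per-day twilight estimates
  (``date,sunrise_utc,sunset_utc``);
* environment and residency surfaces — NetCDF (classic format) with
  ``sst(month,lat,lon)``, ``bathymetry(lat,lon)``, ``land_mask(lat,lon)``
  resp. ``rd(lat,lon)``;
* tracks — CSV ``date,mean_lat,mean_lon,sd_lat,sd_lon``.

Conventions fixed here and used everywhere: longitude in [-180, 180),
latitude in [-90, 90], cell-center registration, timestamps UTC, a "day" is
the UTC calendar day. Readers reject invariant-violating inputs; they never
silently repair them.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from keltrack.errors import FormatError, ValidationError

_TAG_COLUMNS = ["timestamp", "depth_m", "temperature_c"]
_TWL_COLUMNS = ["date", "sunrise_utc", "sunset_utc"]
_TRACK_COLUMNS = ["date", "mean_lat", "mean_lon", "sd_lat", "sd_lon"]

_NETCDF_ENGINE = "scipy"  # classic NetCDF3; no boolean type, land_mask goes as int8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TagDeployment:
    """Release / pop-up metadata for one tagged fish."""

    tag_id: str
    population: str
    release_date: dt.date
    release_lat: float
    release_lon: float
    popup_date: dt.date | None = None
    popup_lat: float | None = None
    popup_lon: float | None = None
    body_length_cm: float | None = None
    body_mass_kg: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.release_lat <= 90.0:
            raise ValidationError(f"release_lat {self.release_lat} outside [-90, 90]")
        if not -180.0 <= self.release_lon < 180.0:
            raise ValidationError(f"release_lon {self.release_lon} outside [-180, 180)")
        if self.popup_date is not None and self.popup_date < self.release_date:
            raise ValidationError("popup_date precedes release_date")
        for name in ("body_length_cm", "body_mass_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")

    def to_dict(self) -> dict:
        d = {
            "tag_id": self.tag_id,
            "population": self.population,
            "release_date": self.release_date.isoformat(),
            "release_lat": self.release_lat,
            "release_lon": self.release_lon,
            "popup_date": self.popup_date.isoformat() if self.popup_date else None,
            "popup_lat": self.popup_lat,
            "popup_lon": self.popup_lon,
            "body_length_cm": self.body_length_cm,
            "body_mass_kg": self.body_mass_kg,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TagDeployment":
        try:
            return cls(
                tag_id=str(d["tag_id"]),
                population=str(d["population"]),
                release_date=dt.date.fromisoformat(d["release_date"]),
                release_lat=float(d["release_lat"]),
                release_lon=float(d["release_lon"]),
                popup_date=(
                    dt.date.fromisoformat(d["popup_date"]) if d.get("popup_date") else None
                ),
                popup_lat=None if d.get("popup_lat") is None else float(d["popup_lat"]),
                popup_lon=None if d.get("popup_lon") is None else float(d["popup_lon"]),
                body_length_cm=(
                    None if d.get("body_length_cm") is None else float(d["body_length_cm"])
                ),
                body_mass_kg=(
                    None if d.get("body_mass_kg") is None else float(d["body_mass_kg"])
                ),
            )
        except KeyError as exc:
            raise FormatError(f"deployment metadata missing field {exc}") from exc


@dataclass
class TagSeries:
    """One tag's time-ordered depth/temperature samples plus twilight events.

    ``samples`` columns: timestamp (tz-aware UTC), depth_m, temperature_c.
    ``twilights`` columns: date, sunrise_utc, sunset_utc (NaT = missing, e.g.
    polar day). Gaps from transmission dropout are allowed; the surviving
    timestamps must remain on the tag's fixed sampling lattice.
    """

    deployment: TagDeployment
    samples: pd.DataFrame
    twilights: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_TWL_COLUMNS))

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sampling_interval_min(self) -> float:
        ts = self.samples["timestamp"]
        if len(ts) < 2:
            return float("nan")
        return float(ts.diff().dropna().min().total_seconds() / 60.0)

    def validate(self) -> None:
        missing = [c for c in _TAG_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"tag series missing columns {missing}")
        depths = self.samples["depth_m"].to_numpy(dtype=float)
        bad = np.flatnonzero(depths < 0)
        if bad.size:
            raise ValidationError(f"negative depth on row(s) {[int(b) + 1 for b in bad]}")
        ts = self.samples["timestamp"]
        if len(ts) >= 2:
            diffs = ts.diff().dropna().dt.total_seconds().to_numpy() / 60.0
            if np.any(diffs <= 0):
                row = int(np.flatnonzero(diffs <= 0)[0]) + 2
                raise ValidationError(f"timestamps not strictly increasing at row {row}")
            base = diffs.min()
            if base < 15.0:
                raise ValidationError(
                    f"sampling interval {base:.1f} min below the 15 min tag minimum"
                )
            if base <= 60.0:
                # base interval observable: dropout gaps must sit on its lattice
                ratio = diffs / base
                if np.any(np.abs(ratio - np.round(ratio)) > 1e-6):
                    raise ValidationError("sample gaps are not multiples of the base interval")

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, TagSeries):
            return NotImplemented
        return (
            self.deployment == other.deployment
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.twilights.reset_index(drop=True).equals(
                other.twilights.reset_index(drop=True)
            )
        )


@dataclass
class EnvironmentGrid:
    """Monthly SST, bathymetry and land mask on a regular lat/lon lattice.

    ``sst`` is indexed (month 1..12, lat, lon) in deg C; ``bathymetry`` is sea
    depth in m, positive at sea; axes hold cell centers.
    """

    lat: np.ndarray
    lon: np.ndarray
    sst: np.ndarray
    bathymetry: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        nlat, nlon = self.lat.size, self.lon.size
        for lbl, axis in (("lat", self.lat), ("lon", self.lon)):
            d = np.diff(axis)
            if axis.size < 1 or not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(f"{lbl} axis empty or not strictly monotone")
        if self.sst.shape != (12, nlat, nlon):
            raise FormatError(f"sst shape {self.sst.shape} != (12, {nlat}, {nlon})")
        if self.bathymetry.shape != (nlat, nlon) or self.land_mask.shape != (nlat, nlon):
            raise FormatError("bathymetry/land_mask shape mismatch with axes")
        ocean = ~self.land_mask
        if np.any(self.bathymetry[ocean] <= 0):
            raise ValidationError("non-positive bathymetry on ocean cells")

    @property
    def resolution_deg(self) -> float:
        for axis in (self.lat, self.lon):
            if axis.size >= 2:
                return float(abs(axis[1] - axis[0]))
        raise ValidationError("grid has a single cell; resolution undefined")

    def nearest_index(self, lat: float, lon: float) -> tuple[int, int]:
        return int(np.argmin(np.abs(self.lat - lat))), int(np.argmin(np.abs(self.lon - lon)))

    def sst_at(self, month: int, lat, lon):
        """Nearest-cell SST lookup; month in 1..12."""
        i = np.argmin(np.abs(self.lat[:, None] - np.atleast_1d(lat)[None, :]), axis=0)
        j = np.argmin(np.abs(self.lon[:, None] - np.atleast_1d(lon)[None, :]), axis=0)
        out = self.sst[month - 1, i, j]
        return float(out[0]) if np.isscalar(lat) else out

    def is_ocean(self, lat: float, lon: float) -> bool:
        i, j = self.nearest_index(lat, lon)
        return not bool(self.land_mask[i, j])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvironmentGrid):
            return NotImplemented
        return (
            np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.sst, other.sst)
            and np.allclose(self.bathymetry, other.bathymetry)
            and np.array_equal(self.land_mask, other.land_mask)
        )


# ---------------------------------------------------------------------------
# tag series I/O
# ---------------------------------------------------------------------------


def _companion_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".meta.json"), path.with_suffix(".twl.csv")


def read_tag_series(path: str | Path) -> TagSeries:
    """Read a tag CSV plus its companion metadata/twilight files.

    Raises FormatError for missing columns/files and ValidationError (naming
    the offending 1-based data rows) for unparseable or invariant-violating
    values.
    """
    path = Path(path)
    meta_path, twl_path = _companion_paths(path)
    if not path.exists():
        raise FormatError(f"tag series file not found: {path}")
    if not meta_path.exists():
        raise FormatError(f"deployment metadata not found: {meta_path}")
    deployment = TagDeployment.from_dict(json.loads(meta_path.read_text()))

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TAG_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    unparseable: set[int] = set()

    def _floats(col: pd.Series, required: bool) -> pd.Series:
        # float() is correctly rounded; pd.to_numeric's fast path is not
        def parse(item: tuple[int, str]) -> float:
            i, x = item
            if x == "":
                if required:
                    unparseable.add(i)
                return np.nan
            try:
                return float(x)
            except ValueError:
                unparseable.add(i)
                return np.nan

        return pd.Series([parse(t) for t in col.items()], index=col.index)

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    depth = _floats(raw["depth_m"], required=True)
    temp = _floats(raw["temperature_c"], required=False)
    unparseable.update(raw.index[ts.isna()])
    if unparseable:
        raise ValidationError(
            f"{path}: unparseable field(s) on row(s) {[i + 1 for i in sorted(unparseable)]}"
        )
    samples = pd.DataFrame({"timestamp": ts, "depth_m": depth, "temperature_c": temp})

    if twl_path.exists():
        twl_raw = pd.read_csv(twl_path, dtype=str, keep_default_na=False)
        miss = [c for c in _TWL_COLUMNS if c not in twl_raw.columns]
        if miss:
            raise FormatError(f"{twl_path}: missing columns {miss}")
        twilights = pd.DataFrame(
            {
                "date": pd.to_datetime(twl_raw["date"], format="%Y-%m-%d").dt.date,
                "sunrise_utc": pd.to_datetime(
                    twl_raw["sunrise_utc"].replace("", None), utc=True, format="ISO8601"
                ),
                "sunset_utc": pd.to_datetime(
                    twl_raw["sunset_utc"].replace("", None), utc=True, format="ISO8601"
                ),
            }
        )
    else:
        twilights = pd.DataFrame(columns=_TWL_COLUMNS)
    return TagSeries(deployment=deployment, samples=samples, twilights=twilights)


def write_tag_series(path: str | Path, series: TagSeries) -> None:
    """Write the CSV + metadata JSON + twilight CSV triple for one tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta_path, twl_path = _companion_paths(path)
    out = series.samples.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    out.to_csv(path, index=False)
    meta_path.write_text(json.dumps(series.deployment.to_dict(), indent=1))
    twl = series.twilights.copy()
    if len(twl):
        twl["date"] = [d.isoformat() for d in twl["date"]]
        for c in ("sunrise_utc", "sunset_utc"):
            twl[c] = twl[c].map(
                lambda t: "" if pd.isna(t) else t.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00")
            )
    twl.to_csv(twl_path, index=False)


# ---------------------------------------------------------------------------
# environment I/O
# ---------------------------------------------------------------------------


def read_environment(path: str | Path) -> EnvironmentGrid:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"environment file not found: {path}")
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        for var in ("sst", "bathymetry", "land_mask"):
            if var not in ds:
                raise FormatError(f"{path}: missing variable '{var}'")
        for coord in ("lat", "lon", "month"):
            if coord not in ds.coords and coord not in ds.variables:
                raise FormatError(f"{path}: missing coordinate '{coord}'")
        grid = EnvironmentGrid(
            lat=ds["lat"].values.copy(),
            lon=ds["lon"].values.copy(),
            sst=ds["sst"].values.copy(),
            bathymetry=ds["bathymetry"].values.copy(),
            land_mask=ds["land_mask"].values.astype(bool).copy(),
        )
    return grid


def write_environment(path: str | Path, env: EnvironmentGrid) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = xr.Dataset(
        {
            "sst": (("month", "lat", "lon"), env.sst),
            "bathymetry": (("lat", "lon"), env.bathymetry),
            "land_mask": (("lat", "lon"), env.land_mask.astype(np.int8)),
        },
        coords={"month": np.arange(1, 13, dtype=np.int32), "lat": env.lat, "lon": env.lon},
    )
    ds["sst"].attrs["units"] = "degC"
    ds["bathymetry"].attrs["units"] = "m"
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


# ---------------------------------------------------------------------------
# track / residency output
# ---------------------------------------------------------------------------


def write_track(path: str | Path, track: pd.DataFrame) -> None:
    """Write daily mean-track summaries (date, mean_lat, mean_lon, sd_lat, sd_lon)."""
    if len(track) == 0:
        raise ValidationError("refusing to write an empty track")
    missing = [c for c in _TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise FormatError(f"track frame missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = track[_TRACK_COLUMNS].copy()
    out["date"] = [d.isoformat() if isinstance(d, dt.date) else str(d) for d in out["date"]]
    out.to_csv(path, index=False)


def read_track(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"track file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_residency(path: str | Path, rd) -> None:
    """Write a residency distribution as NetCDF ``rd(lat, lon)``.

    ``rd`` is any object exposing ``to_dataarray() -> xr.DataArray`` with dims
    (lat, lon) — normally a :class:`keltrack.residency.ResidencyDistribution`.
    """
    da = rd.to_dataarray()
    vals = da.values
    if np.any(vals < 0):
        raise ValidationError("residency distribution has negative cells")
    if abs(float(vals.sum()) - 1.0) > 1e-9:
        raise ValidationError(f"residency distribution sums to {vals.sum()!r}, not 1")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    da.to_dataset(name="rd").to_netcdf(path, engine=_NETCDF_ENGINE)


def read_residency(path: str | Path) -> xr.DataArray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"residency file not found: {path}")
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        if "rd" not in ds:
            raise FormatError(f"{path}: missing variable 'rd'")
        da = ds["rd"].load().copy()
    return da
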