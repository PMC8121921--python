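"""Gridded ocean state: grid geometry, field container, NetCDF round-trip.

The physical environment sampled by drifting eggs and larvae is a set of
velocity components (``u`` eastward, ``v`` northward, m s⁻¹) and water
temperature (°C) on a regular rectilinear lon/lat grid, with one or more
fixed depth levels and an hourly-to-daily time axis.  Land cells, when a
mask is present, carry NaN velocities as a "do not sample" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .errors import ParseError, ValidationError

__all__ = ["GridSpec", "GriddedOceanField", "write_field", "read_field"]

#: physically sane sea-water temperature range (°C)
TEMP_RANGE = (-2.0, 45.0)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectilinear lon/lat(/depth/time) grid.

    Longitudes are degrees east in [-180, 180), latitudes degrees north.
    ``depth_levels`` are metres below the surface, strictly increasing from
    the surface down.  The time axis is in hours from the experiment origin.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_lon: int
    n_lat: int
    depth_levels: tuple[float, ...] = (0.0,)
    time_start: float = 0.0
    time_step: float = 1.0  # hours
    n_times: int = 24

    def __post_init__(self) -> None:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValidationError("grid needs at least 2 cells per horizontal axis")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValidationError("grid axes must be strictly monotone (min < max)")
        if self.time_step <= 0:
            raise ValidationError("time_step must be positive")
        if self.n_times < 2:
            raise ValidationError("time axis needs at least 2 samples")
        d = np.asarray(self.depth_levels, dtype=float)
        if d.size < 1 or np.any(np.diff(d) <= 0) or d[0] < 0:
            raise ValidationError("depth levels must be >=1, non-negative, strictly increasing")

    # -- derived axes ----------------------------------------------------
    @property
    def lons(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat)

    @property
    def depths(self) -> np.ndarray:
        return np.asarray(self.depth_levels, dtype=float)

    @property
    def n_depth(self) -> int:
        return len(self.depth_levels)

    @property
    def times_h(self) -> np.ndarray:
        return self.time_start + self.time_step * np.arange(self.n_times)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(time, depth, lat, lon) array shape."""
        return (self.n_times, self.n_depth, self.n_lat, self.n_lon)

    @property
    def cell_width_deg(self) -> tuple[float, float]:
        """(dlat, dlon) spacing in degrees."""
        return (
            (self.lat_max - self.lat_min) / (self.n_lat - 1),
            (self.lon_max - self.lon_min) / (self.n_lon - 1),
        )

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


@dataclass
class GriddedOceanField:
    """Velocity + temperature arrays on a :class:`GridSpec`.

    All arrays have shape ``grid.shape`` = (time, depth, lat, lon).  On land
    cells (where ``land_mask`` is True) ``u`` and ``v`` hold NaN sentinels
    and must not be sampled; temperature stays defined everywhere so that
    interpolation near the coast remains finite.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    temperature: np.ndarray
    w: np.ndarray | None = None
    land_mask: np.ndarray | None = None  # (lat, lon) boolean
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("u", "v", "temperature"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected {shape} from grid"
                )
        if self.w is not None and self.w.shape != shape:
            raise ValidationError("w shape inconsistent with grid")
        if self.land_mask is not None:
            if self.land_mask.shape != shape[2:]:
                raise ValidationError("land_mask must be (lat, lon)")
            water = ~self.land_mask
        else:
            water = np.ones(shape[2:], dtype=bool)
        wsel = (slice(None), slice(None)) + np.nonzero(water)
        for name in ("u", "v", "temperature"):
            vals = getattr(self, name)[wsel]
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"{name} has non-finite values on water cells")
        t = self.temperature[wsel]
        if t.min() < TEMP_RANGE[0] or t.max() > TEMP_RANGE[1]:
            raise ValidationError(
                f"temperature outside physical range {TEMP_RANGE} on water cells"
            )

    # -- xarray bridge ---------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        coords = {
            "time": ("time", g.times_h, {"units": "hours", "long_name": "time since origin"}),
            "depth": ("depth", g.depths, {"units": "m", "positive": "down"}),
            "lat": ("lat", g.lats, {"units": "degrees_north"}),
            "lon": ("lon", g.lons, {"units": "degrees_east"}),
        }
        dims = ("time", "depth", "lat", "lon")
        data = {
            "u": (dims, self.u, {"units": "m s-1", "long_name": "eastward velocity"}),
            "v": (dims, self.v, {"units": "m s-1", "long_name": "northward velocity"}),
            "temp": (dims, self.temperature, {"units": "degC", "long_name": "water temperature"}),
        }
        if self.w is not None:
            data["w"] = (dims, self.w, {"units": "m s-1", "long_name": "vertical velocity"})
        if self.land_mask is not None:
            data["mask"] = (("lat", "lon"), self.land_mask.astype("i1"),
                            {"long_name": "land mask (1 = land)"})
        return xr.Dataset(data, coords=coords, attrs=dict(self.attrs))

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "GriddedOceanField":
        for dim in ("time", "depth", "lat", "lon"):
            if dim not in ds.dims:
                raise ParseError(f"field file is missing dimension '{dim}'")
        for var in ("u", "v", "temp"):
            if var not in ds.data_vars:
                raise ParseError(f"field file is missing variable '{var}'")
        lons = ds["lon"].values
        lats = ds["lat"].values
        times = ds["time"].values.astype(float)
        for name, ax in (("lon", lons), ("lat", lats), ("time", times)):
            steps = np.diff(ax)
            if ax.size < 2 or not np.allclose(steps, steps[0]):
                raise ParseError(f"axis '{name}' is not uniformly spaced")
        grid = GridSpec(
            lon_min=float(lons[0]), lon_max=float(lons[-1]),
            lat_min=float(lats[0]), lat_max=float(lats[-1]),
            n_lon=lons.size, n_lat=lats.size,
            depth_levels=tuple(float(z) for z in ds["depth"].values),
            time_start=float(times[0]),
            time_step=float(times[1] - times[0]),
            n_times=times.size,
        )
        mask = ds["mask"].values.astype(bool) if "mask" in ds else None
        w = ds["w"].values if "w" in ds else None
        return cls(
            grid=grid,
            u=ds["u"].values,
            v=ds["v"].values,
            temperature=ds["temp"].values,
            w=w,
            land_mask=mask,
            attrs=dict(ds.attrs),
        )


def write_field(fld: GriddedOceanField, path: str | Path) -> None:
    """Write a field to NetCDF with named dims (time, depth, lat, lon)."""
    fld.to_dataset().to_netcdf(path)


def read_field(path: str | Path) -> GriddedOceanField:
    """Read a field written by :func:`write_field` (lossless round-trip)."""
    with xr.open_dataset(Path(path)) as ds:
        return GriddedOceanField.from_dataset(ds.load())
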