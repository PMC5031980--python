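"""Gridded environmental covariate stacks.

An :class:`EnvFieldStack` holds the ten oceanographic covariates on a regular
lon/lat grid (cell centers, decimal degrees, WGS84): eight dated layers
(``sst``, ``sst_sd``, ``chl``, ``ssha``, ``ssha_sd``, ``eke``, ``wekman``,
``uy10``) and two static layers (``bathy``, ``bathy_sd``).  Bathymetry is
negative down; water is ``bathy < 0``.  chl and eke are strictly positive
wherever defined because they are log-transformed downstream.

The container wraps an :class:`xarray.Dataset` and round-trips through
CF-style NetCDF (lon/lat/time coordinate variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

#: Dated covariates carried on the ``time`` axis.
DYNAMIC_VARS = ("sst", "sst_sd", "chl", "ssha", "ssha_sd", "eke", "wekman", "uy10")
#: Date-invariant covariates.
STATIC_VARS = ("bathy", "bathy_sd")
#: Covariates that are log-transformed after extraction.
LOG_VARS = ("chl", "eke")


@dataclass
class EnvFieldStack:
    """Regular-grid stack of environmental covariate layers."""

    data: xr.Dataset

    def __post_init__(self) -> None:
        for v in DYNAMIC_VARS:
            if v not in self.data:
                raise ValueError(f"missing dynamic layer {v!r}")
            if self.data[v].dims != ("time", "lat", "lon"):
                raise ValueError(f"layer {v!r} must have dims (time, lat, lon)")
        for v in STATIC_VARS:
            if v not in self.data:
                raise ValueError(f"missing static layer {v!r}")
            if self.data[v].dims != ("lat", "lon"):
                raise ValueError(f"layer {v!r} must have dims (lat, lon)")
        if self.data.sizes["time"] < 1:
            raise ValueError("stack needs at least one date")

    # -- grid geometry -------------------------------------------------
    @property
    def lons(self) -> np.ndarray:
        return np.asarray(self.data["lon"].values, dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.asarray(self.data["lat"].values, dtype=float)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def resolution(self) -> float:
        lons = self.lons
        return float(lons[1] - lons[0]) if lons.size > 1 else float(
            self.lats[1] - self.lats[0]
        )

    @property
    def bounds(self):
        """(lon_min, lon_max, lat_min, lat_max) of cell *edges*."""
        half = self.resolution / 2.0
        return (
            float(self.lons.min() - half),
            float(self.lons.max() + half),
            float(self.lats.min() - half),
            float(self.lats.max() + half),
        )

    def in_domain(self, lon: float, lat: float) -> bool:
        w, e, s, n = self.bounds
        return (w <= lon <= e) and (s <= lat <= n)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(lat_index, lon_index) of the grid cell containing the position."""
        if not self.in_domain(lon, lat):
            raise ValueError(f"position ({lon}, {lat}) outside grid domain")
        lons, lats = self.lons, self.lats
        res_lon = lons[1] - lons[0] if lons.size > 1 else self.resolution
        res_lat = lats[1] - lats[0] if lats.size > 1 else self.resolution
        i = int(np.clip(round((lat - lats[0]) / res_lat), 0, lats.size - 1))
        j = int(np.clip(round((lon - lons[0]) / res_lon), 0, lons.size - 1))
        return i, j

    def nearest_date_index(self, date) -> int:
        t = pd.Timestamp(date)
        cache = self.__dict__.setdefault("_date_index_cache", {})
        hit = cache.get(t)
        if hit is None:
            hit = cache[t] = int(np.argmin(np.abs(self.dates - t)))
        return hit

    # -- value access --------------------------------------------------
    def layer(self, var: str, date=None) -> np.ndarray:
        """2-D (lat, lon) array for one covariate, nearest-date for dynamics."""
        if var in STATIC_VARS:
            return np.asarray(self.data[var].values, dtype=float)
        k = self.nearest_date_index(date)
        return np.asarray(self.data[var].values[k], dtype=float)

    def value_at(self, var: str, lon: float, lat: float, date=None) -> float:
        i, j = self.cell_index(lon, lat)
        return float(self.layer(var, date)[i, j])

    @property
    def water_mask(self) -> np.ndarray:
        """Boolean (lat, lon) array, True over water (bathy < 0)."""
        return np.asarray(self.data["bathy"].values, dtype=float) < 0.0

    def is_water(self, lon: float, lat: float) -> bool:
        if not self.in_domain(lon, lat):
            return False
        i, j = self.cell_index(lon, lat)
        return bool(self.water_mask[i, j])

    # -- IO --------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        # scipy backend writes classic NetCDF3: no 64-bit ints
        enc = {"time": {"dtype": "float64", "units": "days since 2000-01-01"}}
        ds.to_netcdf(path, engine="scipy", encoding=enc)

    @classmethod
    def from_netcdf(cls, path) -> "EnvFieldStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())
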