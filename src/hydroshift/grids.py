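"""Monthly gridded fields.

Grids are :class:`xarray.DataArray` objects with dims ``("month", "lat",
"lon")``; the ``month`` coordinate holds ``"YYYY-MM"`` string keys and
``lat``/``lon`` hold cell-center coordinates in degrees. This mirrors the
structure of reanalysis products (monthly frequency, regular lat/lon
grid) without committing to a particular file backend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ValidationError
from .geo import haversine_km

MonthlyGrid = xr.DataArray


def make_grid(values: np.ndarray, months, lat, lon, name: str = "value",
              units: str | None = None) -> MonthlyGrid:
    values = np.asarray(values)
    months = np.asarray(list(months))
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if values.shape != (months.size, lat.size, lon.size):
        raise ValidationError(
            f"grid shape {values.shape} does not match (month, lat, lon) = "
            f"({months.size}, {lat.size}, {lon.size})")
    da = xr.DataArray(values, dims=("month", "lat", "lon"),
                      coords={"month": months, "lat": lat, "lon": lon}, name=name)
    if units:
        da.attrs["units"] = units
    return da


def cells_within_radius(grid_like, lat0: float, lon0: float, radius_km: float):
    """Indices ``(ii, jj)`` of cells whose centers lie within ``radius_km``.

    ``grid_like`` is a DataArray or a ``(lat, lon)`` pair of coordinate
    arrays. A latitude/longitude bounding box prefilters candidates
    before the exact haversine test, which keeps the query cheap on fine
    grids.
    """
    if isinstance(grid_like, tuple):
        lat, lon = (np.asarray(a, dtype=float) for a in grid_like)
    else:
        lat = np.asarray(grid_like["lat"].values, dtype=float)
        lon = np.asarray(grid_like["lon"].values, dtype=float)
    dlat = radius_km / 110.0  # slightly generous degree bound
    coslat = max(np.cos(np.radians(lat0)), 1e-3)
    dlon = radius_km / (110.0 * coslat)
    ii_c = np.nonzero(np.abs(lat - lat0) <= dlat)[0]
    jj_c = np.nonzero(np.abs(lon - lon0) <= dlon)[0]
    if ii_c.size == 0 or jj_c.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    lat2d, lon2d = np.meshgrid(lat[ii_c], lon[jj_c], indexing="ij")
    d = haversine_km(lat2d, lon2d, lat0, lon0)
    sel = d <= radius_km
    return ii_c[np.nonzero(sel)[0]], jj_c[np.nonzero(sel)[1]]


def grid_months(grid: MonthlyGrid) -> list[str]:
    return [str(m) for m in grid["month"].values]


def grid_to_long(grid: MonthlyGrid, value_name: str | None = None) -> pd.DataFrame:
    """Long-format table (lat, lon, month, value) for text serialization."""
    name = value_name or grid.name or "value"
    df = grid.to_dataframe(name=name).reset_index()
    return df[["lat", "lon", "month", name]]


def long_to_grid(df: pd.DataFrame, value_name: str) -> MonthlyGrid:
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    months = sorted(df["month"].unique())
    pivot = df.set_index(["month", "lat", "lon"])[value_name].unstack(["lat", "lon"])
    values = np.full((len(months), lat.size, lon.size), np.nan)
    for k, m in enumerate(months):
        values[k] = pivot.loc[m].values.reshape(lat.size, lon.size)
    return make_grid(values, months, lat, lon, name=value_name)


def write_netcdf(grid: MonthlyGrid, path) -> None:
    # NetCDF3 via the scipy engine; month keys stored as fixed-width strings.
    grid.to_dataset(name=grid.name or "value").to_netcdf(path, engine="scipy")


def read_netcdf(path, name: str | None = None) -> MonthlyGrid:
    ds = xr.open_dataset(path, engine="scipy")
    var = name or list(ds.data_vars)[0]
    da = ds[var].load()
    da = da.assign_coords(month=[str(m) for m in da["month"].values])
    return da
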