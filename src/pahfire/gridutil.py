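"""Shared grid helpers: regular lat-lon grids, cell areas, calendar constants."""

from __future__ import annotations

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6.371e6

#: Days per month, non-leap calendar.
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
SECONDS_IN_MONTH = DAYS_IN_MONTH * 86400.0


def regular_grid(nlat: int, nlon: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centered global regular grid; latitude ascending, longitude in [-180, 180)."""
    dlat = 180.0 / nlat
    dlon = 360.0 / nlon
    lat = -90.0 + dlat * (np.arange(nlat) + 0.5)
    lon = -180.0 + dlon * (np.arange(nlon) + 0.5)
    return lat, lon


def cell_area_m2(lat: np.ndarray, lon: np.ndarray) -> xr.DataArray:
    """Exact spherical area (m^2) of each cell of a regular lat-lon grid.

    Cells are assumed cell-centered with uniform spacing inferred from the
    coordinate vectors (a single row/column falls back to global extent).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.diff(lat).mean() if lat.size > 1 else 180.0
    dlon = np.diff(lon).mean() if lon.size > 1 else 360.0
    lat_n = np.deg2rad(np.clip(lat + dlat / 2.0, -90.0, 90.0))
    lat_s = np.deg2rad(np.clip(lat - dlat / 2.0, -90.0, 90.0))
    band = EARTH_RADIUS_M**2 * np.deg2rad(dlon) * (np.sin(lat_n) - np.sin(lat_s))
    area = np.repeat(band[:, None], lon.size, axis=1)
    return xr.DataArray(area, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), attrs={"units": "m2"})


def area_weights(lat: np.ndarray, lon: np.ndarray) -> xr.DataArray:
    """cos(latitude) area weights on the grid, normalized to mean 1."""
    w = np.cos(np.deg2rad(np.asarray(lat, dtype=float)))
    w2d = np.repeat(w[:, None], np.asarray(lon).size, axis=1)
    w2d = w2d / w2d.mean()
    return xr.DataArray(w2d, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))


def round_sigfigs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))
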