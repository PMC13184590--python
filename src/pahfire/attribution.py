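"""Scenario differencing: isolate the fire effect as baseline minus
no-wildfire, with regional, phase and meteorological summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .fate_boxmodel import ConcentrationState, EnvironmentFields, GridMismatchError
from .gridutil import area_weights


@dataclass(frozen=True)
class RegionMask:
    """Named boolean cell mask (at least one true cell)."""

    name: str
    mask: xr.DataArray

    def __post_init__(self) -> None:
        if not bool(self.mask.any()):
            raise ValueError(f"region {self.name!r} selects no cells")


def load_region_masks(path: str | Path, lat, lon) -> list[RegionMask]:
    """Build region masks from a CSV of lat-lon boxes
    (columns: region, lat_min, lat_max, lon_min, lon_max)."""
    df = pd.read_csv(path, comment="#")
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    masks = []
    for row in df.itertuples(index=False):
        inside = (
            (lat2d >= row.lat_min)
            & (lat2d <= row.lat_max)
            & (lon2d >= row.lon_min)
            & (lon2d <= row.lon_max)
        )
        masks.append(
            RegionMask(
                name=str(row.region),
                mask=xr.DataArray(inside, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")),
            )
        )
    return masks


@dataclass(frozen=True)
class AttributionField:
    """Fire-attributed concentration per cell.

    ``absolute`` = baseline - nowf (ng m-3); ``percent`` = 100 * absolute /
    baseline where baseline > 0; ``defined`` flags cells where the percent is
    meaningful (baseline > 0). Cells where nowf exceeds baseline are kept as
    negative values, never clipped.
    """

    absolute: xr.DataArray
    percent: xr.DataArray
    defined: xr.DataArray
    year: str = ""

    def to_netcdf(self, path: str | Path) -> None:
        ds = xr.Dataset(
            {
                "absolute": self.absolute,
                "percent": self.percent,
                "defined": self.defined.astype(np.int8),
            },
            attrs={"year": self.year},
        )
        ds["absolute"].attrs["units"] = "ng m-3"
        ds["percent"].attrs["units"] = "%"
        ds.to_netcdf(path, engine="scipy")


def _check_same_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    if not (
        np.array_equal(a.lat.values, b.lat.values)
        and np.array_equal(a.lon.values, b.lon.values)
    ):
        raise GridMismatchError("grids differ")


def fire_contribution(
    baseline: ConcentrationState, nowf: ConcentrationState, year: str = ""
) -> AttributionField:
    """Fire-attributed all-species, all-phase concentration per cell."""
    _check_same_grid(baseline.conc, nowf.conc)
    if baseline.species != nowf.species:
        raise ValueError("species lists differ between scenarios")
    base = baseline.total().sum(dim="species")
    now = nowf.total().sum(dim="species")
    absolute = base - now
    defined = base > 0
    percent = xr.where(defined, 100.0 * absolute / base.where(defined), np.nan)
    return AttributionField(absolute=absolute, percent=percent, defined=defined, year=year)


def area_weighted_mean(field: xr.DataArray, mask: RegionMask | xr.DataArray | None = None) -> float:
    """Mean of a (lat, lon) field weighted by cos(latitude) cell area,
    optionally restricted to a region mask."""
    w = area_weights(field.lat.values, field.lon.values)
    if mask is not None:
        m = mask.mask if isinstance(mask, RegionMask) else mask
        if not bool(m.any()):
            raise ValueError("empty mask")
        w = w.where(m, 0.0)
    denom = float(w.sum())
    if denom == 0:
        raise ValueError("empty mask")
    return float((field * w).sum() / denom)


def regional_summary(
    baseline: ConcentrationState,
    nowf: ConcentrationState,
    regions: list[RegionMask],
    year: str = "",
) -> pd.DataFrame:
    """Area-weighted absolute and percent fire contribution per region."""
    attr = fire_contribution(baseline, nowf, year=year)
    base = baseline.total().sum(dim="species")
    rows = []
    for region in regions:
        absolute = area_weighted_mean(attr.absolute, region)
        base_mean = area_weighted_mean(base, region)
        percent = 100.0 * absolute / base_mean if base_mean > 0 else np.nan
        rows.append(
            {"region": region.name, "absolute_ng_m3": absolute, "percent": percent, "year": year}
        )
    return pd.DataFrame(rows)


def phase_fractions(state: ConcentrationState) -> dict[str, float]:
    """Global area-weighted composition of a state.

    ``gas_fraction`` and ``particle_fraction`` partition the parent (all
    species summed) concentration and sum to 1. ``npah_fraction`` and
    ``dnpah_fraction`` are shares of the grand total including the diagnosed
    degradation products.
    """
    w = area_weights(state.ds.lat.values, state.ds.lon.values)
    gas = float((state.gas().sum(dim="species") * w).sum())
    particle = float((state.particle().sum(dim="species") * w).sum())
    npah = float((state.npah.sum(dim="species") * w).sum())
    dnpah = float((state.dnpah.sum(dim="species") * w).sum())
    parent_total = gas + particle
    grand_total = parent_total + npah + dnpah
    if parent_total <= 0 or grand_total <= 0:
        raise ValueError("zero total burden")
    return {
        "gas_fraction": gas / parent_total,
        "particle_fraction": particle / parent_total,
        "npah_fraction": npah / grand_total,
        "dnpah_fraction": dnpah / grand_total,
    }


def difference_state(baseline: ConcentrationState, nowf: ConcentrationState) -> ConcentrationState:
    """Per-variable baseline - nowf state (the fire-sourced mixture).

    Small negative differences are possible in scenario-specific-oxidant
    mode; they are preserved in the data but the returned object bypasses the
    non-negativity check, flagged via its period label.
    """
    _check_same_grid(baseline.conc, nowf.conc)
    ds = baseline.ds.copy()
    for name in ("conc", "npah", "dnpah"):
        ds[name] = baseline.ds[name] - nowf.ds[name]
    obj = object.__new__(ConcentrationState)
    object.__setattr__(obj, "ds", ds)
    object.__setattr__(obj, "period", f"difference({baseline.period})")
    return obj


def meteorology_difference(
    fields_a: EnvironmentFields,
    fields_b: EnvironmentFields,
    land: xr.DataArray | None = None,
) -> dict[str, float]:
    """Per-variable time-mean(a) - time-mean(b), area-weight-averaged over
    land cells."""
    if not (
        np.array_equal(fields_a.lat, fields_b.lat)
        and np.array_equal(fields_a.lon, fields_b.lon)
    ):
        raise GridMismatchError("environment grids differ")
    if land is None:
        land = fields_a.land_mask
    if not bool(land.any()):
        raise ValueError("empty land mask")
    out = {}
    for name in EnvironmentFields._MONTHLY:
        delta = fields_a.ds[name].mean(dim="month") - fields_b.ds[name].mean(dim="month")
        out[name] = area_weighted_mean(delta, land)
    return out
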