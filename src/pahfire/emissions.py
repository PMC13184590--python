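"""Emission-inventory data model and fire-sector operations.

The inventory is a dense (sector, species, month, lat, lon) array of emitted
mass per cell per month. The module implements the fire-sector speciation
redistribution (annual fire mass, excluding NAP, moved entirely onto the 3-
and 4-ring species while preserving their relative proportions), scenario
construction (fires switched off), and sector ring-size composition
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .species_registry import SpeciesRegistry

#: The eight inventory sectors, fixed.
SECTORS = (
    "residential",
    "agricultural",
    "industrial_processes",
    "industrial_combustion",
    "transportation",
    "commercial",
    "fires",
    "electric_generation",
)

FIRE_SECTOR = "fires"
NAP = "NAP"

_DIMS = ("sector", "species", "month", "lat", "lon")


class InventoryError(ValueError):
    """Raised when an inventory violates a structural invariant."""


@dataclass(frozen=True)
class EmissionInventory:
    """Sector x species x month x grid emission masses (kg per cell per month)."""

    data: xr.DataArray
    year: str = ""

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != _DIMS:
            raise InventoryError(f"inventory dims must be {_DIMS}, got {tuple(self.data.dims)}")
        if set(self.data.sector.values.tolist()) != set(SECTORS):
            raise InventoryError(f"sector coordinate must be exactly {sorted(SECTORS)}")
        vals = self.data.values
        if not np.isfinite(vals).all():
            raise InventoryError("inventory contains non-finite values")
        if (vals < 0).any():
            raise InventoryError("inventory contains negative values")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.species.values]

    def fires(self) -> xr.DataArray:
        return self.data.sel(sector=FIRE_SECTOR)

    def annual_totals(self, sector: str) -> xr.DataArray:
        """Annual emission per species (kg) summed over months and cells."""
        return self.data.sel(sector=sector).sum(dim=("month", "lat", "lon"))

    def total(self) -> float:
        return float(self.data.sum())

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.data.to_dataset(name="emissions")
        ds["emissions"].attrs["units"] = "kg/cell/month"
        ds.attrs.update(
            {
                "year": self.year,
                "grid_convention": "cell-centered regular lat-lon, degrees, latitude ascending",
            }
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "EmissionInventory":
        with xr.open_dataset(path, engine="scipy") as ds:
            data = ds["emissions"].load()
            year = str(ds.attrs.get("year", ""))
        return cls(data=data.transpose(*_DIMS), year=year)

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (sector, species, month, lat, lon, kg) for toy cases."""
        df = self.data.to_series().rename("kg").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, year: str = "") -> "EmissionInventory":
        df = pd.read_csv(path, comment="#")
        da = df.set_index(list(_DIMS))["kg"].to_xarray().fillna(0.0)
        da = da.reindex(sector=list(SECTORS), fill_value=0.0)
        return cls(data=da.transpose(*_DIMS), year=year)


def inventory_from_values(
    values: np.ndarray,
    species: list[str],
    lat: np.ndarray,
    lon: np.ndarray,
    year: str = "",
) -> EmissionInventory:
    """Build an inventory from a dense (sector, species, month, lat, lon) array."""
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        coords={
            "sector": list(SECTORS),
            "species": species,
            "month": np.arange(1, 13),
            "lat": np.asarray(lat, dtype=float),
            "lon": np.asarray(lon, dtype=float),
        },
        dims=_DIMS,
    )
    return EmissionInventory(data=da, year=year)


def total_fire_pah_excluding_nap(inv: EmissionInventory) -> float:
    """Total annual fire-sector PAH emission (kg) summed over every species
    except NAP, all months and all cells."""
    fires = inv.fires()
    keep = [s for s in inv.species if s != NAP]
    return float(fires.sel(species=keep).sum())


def species_fractions(inv: EmissionInventory, subset: list[str]) -> dict[str, float]:
    """Fractional contribution of each subset species to the subset's total
    annual fire-sector emission: f_i = E_i / sum(E)."""
    if not subset:
        raise ValueError("subset must be non-empty")
    annual = inv.annual_totals(FIRE_SECTOR).sel(species=list(subset))
    total = float(annual.sum())
    if total <= 0:
        raise ValueError("no basis for fractions: subset fire emission total is zero")
    return {str(s): float(annual.sel(species=s)) / total for s in subset}


def redistribute_fire_speciation(
    inv: EmissionInventory, registry: SpeciesRegistry
) -> EmissionInventory:
    """Reassign fire-sector emissions so only 2-4 ring species are emitted.

    NAP is held constant cell-by-cell and month-by-month. The annual
    fire-sector total excluding NAP is redistributed onto the 3- and 4-ring
    species in proportion to their original annual fire emissions
    (E'_i = f_i * E_total), which conserves the non-NAP total and preserves
    relative proportions within the group. Each species keeps its original
    monthly/spatial fire pattern, scaled by E'_i / E_i. 5- and 6-ring fire
    emissions become zero. Non-fire sectors are returned bit-identical.
    """
    group = [s for s in registry.by_ring_count({3, 4}) if s in inv.species]
    heavy = [s for s in registry.by_ring_count({5, 6}) if s in inv.species]
    if not group:
        raise ValueError("no 3-/4-ring species present in the inventory")

    annual = inv.annual_totals(FIRE_SECTOR)
    group_total = float(annual.sel(species=group).sum())
    if group_total <= 0:
        raise ValueError("all 3-/4-ring fire emissions are zero; cannot form fractions")

    e_total = total_fire_pah_excluding_nap(inv)
    data = inv.data.copy(deep=True)
    # scale = (f_i * E_total) / E_i is the same for every group member, so each
    # species keeps its original monthly/spatial fire pattern
    scale = e_total / group_total
    for s in group:
        data.loc[{"sector": FIRE_SECTOR, "species": s}] = (
            data.sel(sector=FIRE_SECTOR, species=s) * scale
        )
    for s in heavy:
        data.loc[{"sector": FIRE_SECTOR, "species": s}] = 0.0
    return replace(inv, data=data)


def zero_fire_emissions(inv: EmissionInventory) -> EmissionInventory:
    """No-wildfire scenario: fire-sector emissions all zero, other sectors
    bit-identical."""
    data = inv.data.copy(deep=True)
    data.loc[{"sector": FIRE_SECTOR}] = 0.0
    return replace(inv, data=data)


def sector_ring_composition(
    inv: EmissionInventory,
    registry: SpeciesRegistry,
    exclude: tuple[str, ...] = (NAP,),
) -> pd.DataFrame:
    """Annual emission fraction per sector from 3-, 4-, 5- and 6-ring parents.

    Species in ``exclude`` (default: NAP) are left out. Rows are sectors,
    columns ring counts; a sector with zero included emission gets NaN
    fractions (flagged undefined rather than zero).
    """
    ring_of = {s.abbreviation: s.ring_count for s in registry.parents}
    rows = {}
    for sector in SECTORS:
        annual = inv.annual_totals(sector)
        by_ring = {r: 0.0 for r in (3, 4, 5, 6)}
        for sp in inv.species:
            if sp in exclude or sp not in ring_of:
                continue
            r = ring_of[sp]
            if r in by_ring:
                by_ring[r] += float(annual.sel(species=sp))
        total = sum(by_ring.values())
        if total > 0:
            rows[sector] = {r: v / total for r, v in by_ring.items()}
        else:
            rows[sector] = {r: np.nan for r in by_ring}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sector"
    return df
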