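"""Model-observation evaluation: pair point observations to grid cells and
compute the normalized mean bias, per species and per weight class."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .species_registry import SpeciesRegistry, classify_weight_class

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObservationRecord:
    """Annual-mean all-phase concentration at a monitoring site."""

    site_id: str
    latitude: float
    longitude: float
    species: str
    conc_ng_m3: float
    urban: bool = False

    def __post_init__(self) -> None:
        if self.conc_ng_m3 < 0:
            raise ValueError(f"{self.site_id}: concentration must be >= 0")
        if not (-90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 360.0):
            raise ValueError(f"{self.site_id}: coordinates out of range")


def load_observations(path: str | Path) -> list[ObservationRecord]:
    df = pd.read_csv(path, comment="#")
    return [
        ObservationRecord(
            site_id=str(r.site_id),
            latitude=float(r.lat),
            longitude=float(r.lon),
            species=str(r.species),
            conc_ng_m3=float(r.conc_ng_m3),
            urban=bool(r.urban),
        )
        for r in df.itertuples(index=False)
    ]


def write_observations(records: list[ObservationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "lat": r.latitude,
                "lon": r.longitude,
                "species": r.species,
                "conc_ng_m3": r.conc_ng_m3,
                "urban": r.urban,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def pair_to_grid(
    obs: list[ObservationRecord], field: xr.DataArray
) -> tuple[list[tuple[float, float]], int]:
    """Match each observation to the value of its containing grid cell.

    ``field`` is a (species, lat, lon) or (lat, lon) annual-mean
    concentration; the nearest-cell-center rule handles edge sites. Sites
    outside the grid domain (beyond half a cell from the outermost centers)
    or with a species absent from the field are dropped and counted.
    Returns (pairs of (model, observed), number dropped).
    """
    if not obs:
        raise ValueError("empty observation list")
    lat = field.lat.values
    lon = field.lon.values
    dlat = np.diff(lat).mean() if lat.size > 1 else 180.0
    dlon = np.diff(lon).mean() if lon.size > 1 else 360.0
    has_species = "species" in field.dims
    species_available = set(map(str, field.species.values)) if has_species else None

    pairs: list[tuple[float, float]] = []
    dropped = 0
    for record in obs:
        out_of_domain = (
            record.latitude < lat.min() - dlat / 2
            or record.latitude > lat.max() + dlat / 2
            or record.longitude < lon.min() - dlon / 2
            or record.longitude > lon.max() + dlon / 2
        )
        if out_of_domain or (has_species and record.species not in species_available):
            dropped += 1
            continue
        i = int(np.argmin(np.abs(lat - record.latitude)))
        j = int(np.argmin(np.abs(lon - record.longitude)))
        cell = field.isel(lat=i, lon=j)
        if has_species:
            cell = cell.sel(species=record.species)
        pairs.append((float(cell), record.conc_ng_m3))
    if dropped:
        logger.info("pair_to_grid dropped %d out-of-domain records", dropped)
    return pairs, dropped


def normalized_mean_bias(pairs: list[tuple[float, float]]) -> float:
    """NMB (%) = 100 * sum(model - observed) / sum(observed)."""
    model = np.array([m for m, _ in pairs], dtype=float)
    observed = np.array([o for _, o in pairs], dtype=float)
    obs_sum = observed.sum()
    if obs_sum <= 0:
        raise ValueError("sum of observations must be > 0")
    return 100.0 * float((model - observed).sum()) / float(obs_sum)


def nmb_by_species(
    obs: list[ObservationRecord], field: xr.DataArray, registry: SpeciesRegistry
) -> pd.DataFrame:
    """Per-species and LMW/HMW-aggregated NMB table."""
    rows = []
    by_class_pairs: dict[str, list[tuple[float, float]]] = {"LMW": [], "HMW": []}
    species_names = sorted({r.species for r in obs})
    for sp in species_names:
        records = [r for r in obs if r.species == sp]
        pairs, _ = pair_to_grid(records, field)
        if not pairs or sum(o for _, o in pairs) <= 0:
            continue
        nmb = normalized_mean_bias(pairs)
        weight_class = (
            classify_weight_class(registry[sp])
            if sp in registry and registry[sp].species_class == "parent"
            else ""
        )
        rows.append({"group": sp, "kind": "species", "weight_class": weight_class, "nmb_percent": nmb})
        if weight_class:
            by_class_pairs[weight_class].extend(pairs)
    for weight_class, pairs in by_class_pairs.items():
        if pairs and sum(o for _, o in pairs) > 0:
            rows.append(
                {
                    "group": weight_class,
                    "kind": "weight_class",
                    "weight_class": weight_class,
                    "nmb_percent": normalized_mean_bias(pairs),
                }
            )
    return pd.DataFrame(rows)
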