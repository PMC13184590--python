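"""Seeded synthetic inputs with the statistical structure the analysis
assumes: fire emissions concentrated in fire-prone boxes with unimodal
seasonal peaks, anthropogenic emissions at persistent hotspots with winter
residential seasonality, PM and oxidant enhancements co-located with fires
(baseline variant only), and multiplicative-noise observations.

Everything is a pure function of (config, seed). Two packaged "years"
(low-fire, high-fire) differ by a configurable fire mass factor, defaulting
to 1.3.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import xarray as xr

from . import default_regions_path, default_species_table_path
from .emissions import SECTORS, EmissionInventory, inventory_from_values
from .evaluation import ObservationRecord, write_observations
from .fate_boxmodel import EnvironmentFields, make_environment
from .gridutil import regular_grid
from .species_registry import SpeciesRegistry, load_default_registry


@dataclass(frozen=True)
class FireRegionBox:
    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    peak_month: int


DEFAULT_FIRE_REGIONS = (
    FireRegionBox("australia", -40, -12, 112, 154, peak_month=12),
    FireRegionBox("sub_saharan_africa", -12, 12, 8, 42, peak_month=8),
    FireRegionBox("siberia", 48, 68, 78, 132, peak_month=7),
    FireRegionBox("canada", 48, 64, -122, -88, peak_month=7),
)

#: (lat, lon, relative strength) anthropogenic emission hotspots.
DEFAULT_HOTSPOTS = (
    (32.0, 114.0, 1.0),   # east Asia
    (24.0, 80.0, 0.8),    # south Asia
    (50.0, 10.0, 0.5),    # Europe
    (40.0, -90.0, 0.5),   # North America
    (-8.0, -48.0, 0.2),   # South America
    (8.0, 6.0, 0.2),      # west Africa
)


@dataclass(frozen=True)
class SyntheticConfig:
    nlat: int = 36
    nlon: int = 72
    seed: int = 0
    fire_regions: tuple[FireRegionBox, ...] = DEFAULT_FIRE_REGIONS
    hotspots: tuple[tuple[float, float, float], ...] = DEFAULT_HOTSPOTS
    #: annual anthropogenic PAH emission (kg) across all non-fire sectors
    anthropogenic_total_kg: float = 4.7e8
    #: annual fire PAH emission (kg) in the low-fire year
    fire_total_kg: float = 2.5e7
    fire_intensity_scale: float = 1.0
    #: high-fire year emits this factor more fire mass
    high_fire_factor: float = 1.3
    #: peak OC enhancement (ug m-3) where fire emission is strongest
    pm_enhancement: float = 40.0
    #: peak multiplicative NO3 enhancement inside fires
    oxidant_enhancement: float = 8.0
    #: peak multiplicative O3 enhancement inside fires
    o3_enhancement: float = 0.5
    #: signed fractional OH change at peak fire intensity; negative by default
    #: (fire-emitted CO and VOCs act as a net OH sink in plumes)
    oh_plume_factor: float = -0.4
    n_observations: int = 200
    obs_noise_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.nlat < 4 or self.nlon < 4:
            raise ValueError("grid must be at least 4 x 4")
        for name in ("anthropogenic_total_kg", "fire_total_kg", "high_fire_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.oh_plume_factor < -1.0:
            raise ValueError("oh_plume_factor must be >= -1 (OH cannot go negative)")


#: Ring-class emission fractions per sector (3-, 4-, 5-, 6-ring share of the
#: non-NAP emission). The fire sector lies within the range of the others.
_SECTOR_RING_MIX = {
    "residential": (0.45, 0.30, 0.17, 0.08),
    "agricultural": (0.55, 0.30, 0.10, 0.05),
    "industrial_processes": (0.40, 0.32, 0.18, 0.10),
    "industrial_combustion": (0.42, 0.33, 0.16, 0.09),
    "transportation": (0.30, 0.32, 0.24, 0.14),
    "commercial": (0.42, 0.32, 0.17, 0.09),
    "fires": (0.46, 0.31, 0.15, 0.08),
    "electric_generation": (0.44, 0.31, 0.16, 0.09),
}

#: Share of each sector's total emission carried by NAP (the volatile 2-ring
#: species dominates most inventories).
_NAP_SHARE = 0.55

#: Relative share of each sector in the anthropogenic total.
_SECTOR_SHARE = {
    "residential": 0.38,
    "agricultural": 0.08,
    "industrial_processes": 0.12,
    "industrial_combustion": 0.14,
    "transportation": 0.16,
    "commercial": 0.06,
    "electric_generation": 0.06,
}


def _gaussian_bump(lat2d, lon2d, lat0, lon0, sigma_deg):
    dlon = (lon2d - lon0 + 180.0) % 360.0 - 180.0
    return np.exp(-((lat2d - lat0) ** 2 + dlon**2) / (2.0 * sigma_deg**2))


def _seasonal_profile(peak_month: int, width: float = 1.5) -> np.ndarray:
    """Unimodal circular profile over months 1-12, normalized to sum 1."""
    months = np.arange(1, 13)
    d = np.minimum(np.abs(months - peak_month), 12 - np.abs(months - peak_month))
    prof = np.exp(-(d**2) / (2.0 * width**2))
    return prof / prof.sum()


def _species_weights(registry: SpeciesRegistry, ring_mix, rng) -> dict[str, float]:
    """Per-species share of a sector's emission given its ring-class mix."""
    weights: dict[str, float] = {"NAP": _NAP_SHARE}
    remaining = 1.0 - _NAP_SHARE
    for rings, mix in zip((3, 4, 5, 6), ring_mix):
        members = registry.by_ring_count({rings})
        if not members:
            continue
        raw = rng.uniform(0.5, 1.5, size=len(members))
        raw = raw / raw.sum()
        for name, w in zip(members, raw):
            weights[name] = remaining * mix * w
    return weights


def generate_inventory(cfg: SyntheticConfig, year: str = "low") -> EmissionInventory:
    """Synthetic 8-sector x 16-parent x 12-month inventory (kg/cell/month).

    Deterministic given (cfg, cfg.seed, year); the high-fire year scales the
    fire sector by ``cfg.high_fire_factor``.
    """
    if year not in ("low", "high"):
        raise ValueError("year must be 'low' or 'high'")
    rng = np.random.default_rng(cfg.seed)
    registry = load_default_registry()
    species = registry.parent_names()
    lat, lon = regular_grid(cfg.nlat, cfg.nlon)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")

    # anthropogenic spatial pattern: hotspots plus a weak diffuse background
    anthro = np.full_like(lat2d, 0.02)
    for lat0, lon0, strength in cfg.hotspots:
        anthro += strength * _gaussian_bump(lat2d, lon2d, lat0, lon0, 12.0)
    anthro /= anthro.sum()

    winter = _seasonal_profile(1, width=2.5)  # residential heating peak
    flat = np.full(12, 1.0 / 12.0)

    values = np.zeros((len(SECTORS), len(species), 12, cfg.nlat, cfg.nlon))
    for isec, sector in enumerate(SECTORS):
        if sector == "fires":
            continue
        total = cfg.anthropogenic_total_kg * _SECTOR_SHARE[sector]
        weights = _species_weights(registry, _SECTOR_RING_MIX[sector], rng)
        seasonal = winter if sector == "residential" else flat
        for isp, sp in enumerate(species):
            w = weights.get(sp, 0.0)
            values[isec, isp] = w * total * seasonal[:, None, None] * anthro[None, :, :]

    # fire sector: seasonal bumps inside the fire-prone boxes
    fire_total = cfg.fire_total_kg * cfg.fire_intensity_scale
    if year == "high":
        fire_total *= cfg.high_fire_factor
    fire_pattern = np.zeros((12, cfg.nlat, cfg.nlon))
    for region in cfg.fire_regions:
        inside = (
            (lat2d >= region.lat_min)
            & (lat2d <= region.lat_max)
            & (lon2d >= region.lon_min)
            & (lon2d <= region.lon_max)
        )
        lat0 = 0.5 * (region.lat_min + region.lat_max)
        lon0 = 0.5 * (region.lon_min + region.lon_max)
        bump = _gaussian_bump(lat2d, lon2d, lat0, lon0, 10.0) * inside
        seasonal = _seasonal_profile(region.peak_month)
        fire_pattern += seasonal[:, None, None] * bump[None, :, :]
    pattern_sum = fire_pattern.sum()
    if pattern_sum > 0:
        fire_pattern /= pattern_sum
    fire_weights = _species_weights(registry, _SECTOR_RING_MIX["fires"], rng)
    ifire = SECTORS.index("fires")
    for isp, sp in enumerate(species):
        w = fire_weights.get(sp, 0.0)
        values[ifire, isp] = w * fire_total * fire_pattern

    return inventory_from_values(values, species, lat, lon, year=year)


def generate_environment(
    cfg: SyntheticConfig, inv: EmissionInventory
) -> tuple[EnvironmentFields, EnvironmentFields]:
    """(baseline, NoWF) environment pair on the inventory grid.

    The baseline variant adds PM and oxidant enhancements proportional to
    the local monthly fire emission; the NoWF variant carries only the
    backgrounds, so the two are identical wherever (and whenever) there is
    no fire.
    """
    lat = inv.data.lat.values
    lon = inv.data.lon.values
    nlat, nlon = len(lat), len(lon)
    months = np.arange(1, 13)

    lat2d = np.meshgrid(lat, lon, indexing="ij")[0]
    # smooth latitudinal temperature with a hemispheric seasonal cycle
    t_base = 288.0 - 32.0 * (np.abs(lat2d) / 90.0) ** 2
    season = np.cos(2.0 * np.pi * (months[:, None, None] - 7) / 12.0)
    temperature = t_base[None, :, :] + 10.0 * season * (lat2d[None, :, :] / 90.0)

    fire_monthly = inv.fires().sum(dim="species").values  # (12, nlat, nlon)
    peak = fire_monthly.max()
    fire_norm = fire_monthly / peak if peak > 0 else np.zeros_like(fire_monthly)

    oc_bg = np.full((12, nlat, nlon), 4.0)
    bc_bg = np.full((12, nlat, nlon), 1.0)
    oh_bg = 1.0e6 * (0.6 + 0.4 * np.cos(np.deg2rad(lat2d))[None, :, :]) * (
        1.0 + 0.2 * season * np.sign(lat2d)[None, :, :]
    )
    o3_bg = np.full((12, nlat, nlon), 30.0)
    no3_bg = np.full((12, nlat, nlon), 2.5e8)

    def build(enhanced: bool) -> EnvironmentFields:
        boost = fire_norm if enhanced else 0.0
        monthly = {
            "temperature": temperature,
            "oc": oc_bg + cfg.pm_enhancement * boost,
            "bc": bc_bg + 0.25 * cfg.pm_enhancement * boost,
            "oh": oh_bg * (1.0 + cfg.oh_plume_factor * boost),
            "o3": o3_bg * (1.0 + cfg.o3_enhancement * boost),
            "no3": no3_bg * (1.0 + cfg.oxidant_enhancement * boost),
        }
        return make_environment(lat, lon, monthly)

    return build(True), build(False)


def generate_observations(
    truth: xr.DataArray, cfg: SyntheticConfig, species: str | None = None
) -> list[ObservationRecord]:
    """Observation records at seeded random cells with lognormal noise.

    ``truth`` is an annual-mean concentration field with dims (lat, lon) or
    (species, lat, lon); sites sample cells with positive truth values,
    observed = truth * lognormal(0, sigma).
    """
    if (truth.values < 0).any():
        raise ValueError("truth field must be non-negative")
    rng = np.random.default_rng(cfg.seed + 1)
    has_species = "species" in truth.dims
    lat = truth.lat.values
    lon = truth.lon.values
    records = []
    for k in range(cfg.n_observations):
        for _ in range(64):  # rejection-sample a cell with signal
            i = int(rng.integers(len(lat)))
            j = int(rng.integers(len(lon)))
            if has_species:
                sp = str(truth.species.values[rng.integers(truth.sizes["species"])])
                value = float(truth.sel(species=sp).isel(lat=i, lon=j))
            else:
                sp = species or "PAH"
                value = float(truth.isel(lat=i, lon=j))
            if value > 0:
                break
        noise = float(np.exp(rng.normal(0.0, cfg.obs_noise_sigma))) if cfg.obs_noise_sigma > 0 else 1.0
        records.append(
            ObservationRecord(
                site_id=f"site{k:04d}",
                latitude=float(lat[i]),
                longitude=float(lon[j]),
                species=sp,
                conc_ng_m3=value * noise,
                urban=bool(rng.random() < 0.5),
            )
        )
    return records


def write_bundle(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle: inventories for both years,
    baseline/NoWF environments, the species table, region boxes, and a
    placeholder observations file keyed to the low-fire inventory pattern."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for year in ("low", "high"):
        inv = generate_inventory(cfg, year=year)
        paths[f"inventory_{year}"] = outdir / f"inventory_{year}.nc"
        inv.to_netcdf(paths[f"inventory_{year}"])
        baseline_env, nowf_env = generate_environment(cfg, inv)
        paths[f"env_{year}_baseline"] = outdir / f"env_{year}_baseline.nc"
        paths[f"env_{year}_nowf"] = outdir / f"env_{year}_nowf.nc"
        baseline_env.to_netcdf(paths[f"env_{year}_baseline"])
        nowf_env.to_netcdf(paths[f"env_{year}_nowf"])

    paths["species"] = outdir / "species.csv"
    shutil.copyfile(default_species_table_path(), paths["species"])
    paths["regions"] = outdir / "regions.csv"
    shutil.copyfile(default_regions_path(), paths["regions"])

    # observations against a crude emission-proportional proxy field so the
    # evaluation stage has input before any simulation has run
    inv_low = generate_inventory(cfg, year="low")
    proxy = inv_low.data.sum(dim=("sector", "month"))
    proxy = proxy / max(float(proxy.max()), 1e-30)
    records = generate_observations(proxy, cfg)
    paths["observations"] = outdir / "observations.csv"
    write_observations(records, paths["observations"])
    return paths
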