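"""Per-cell PAH fate box model.

Each grid cell is an independent well-mixed box: emissions enter the gas
phase, gas/particle phases exchange by instantaneous equilibrium
partitioning (poly-parameter linear free energy scheme), the gas phase is
lost to OH photooxidation, NO3 nitration and deposition, and the particle
phase to heterogeneous ozonolysis and deposition. Nitro- and dinitro-PAH
concentrations are diagnosed from the local steady-state nitro-pyrene
pathway ratios, applied uniformly to all parents.

Within each time step the kinetic update is the exact exponential solution
of the per-phase linear ODEs (not forward Euler); phases are re-equilibrated
after every step. Everything is linear in emissions and concentrations for a
fixed environment, so scenario differencing obeys superposition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .gridutil import SECONDS_IN_MONTH, cell_area_m2
from .species_registry import SpeciesDescriptor, SpeciesRegistry

PHASES = ("gas", "particle_oc", "particle_bc")

T_REF = 298.15

NG_PER_KG = 1.0e12


class GridMismatchError(ValueError):
    """Raised when inventory/environment/state grids disagree."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PplferSystem:
    """System coefficients of the partitioning scheme.

    log10 Kp = intercept + dot(coefficients, descriptors)
             + temperature_slope * (1000/T - 1000/T_ref)

    ``temperature_slope`` must be positive so Kp strictly decreases with
    temperature (volatility rises with warmth).
    """

    intercept: float = -11.5
    coefficients: tuple[float, ...] = (0.2, 0.3, 0.5, 0.6, 0.75)
    temperature_slope: float = 4.0

    def __post_init__(self) -> None:
        if self.temperature_slope <= 0:
            raise ValueError("temperature_slope must be > 0 (Kp must decrease with T)")


@dataclass(frozen=True)
class FateConfig:
    """Box-model constants; all overridable per run."""

    dt_seconds: float = 3600.0
    spinup_months: int = 2
    pplfer: PplferSystem = field(default_factory=PplferSystem)
    #: heterogeneous O3 loss: k_het = gamma_o3 * k_het_per_ppb * [O3 in ppb]
    k_het_per_ppb: float = 2.0e-4
    #: nitro-pyrene pathway (sequential first-order nitration with yields)
    nitration_yield: float = 0.8
    dinitration_yield: float = 0.8
    k_second_nitration: float = 8.0e-14  # cm3 molecule-1 s-1, NPAH + NO3
    k_oh_npah: float = 3.0e-11  # cm3 molecule-1 s-1, NPAH loss to OH
    k_oh_dnpah: float = 1.0e-11  # cm3 molecule-1 s-1, DNPAH loss to OH
    k_loss_floor: float = 1.0e-6  # s-1, floor on product loss rates


# ---------------------------------------------------------------------------
# environment and state containers


@dataclass(frozen=True)
class EnvironmentFields:
    """Monthly gridded environment: temperature (K), OC/BC PM (ug m-3),
    OH/NO3 number density (molecule cm-3), O3 (ppb), plus mixing height (m),
    first-order deposition rates (s-1) and a land mask."""

    ds: xr.Dataset

    _MONTHLY = ("temperature", "oc", "bc", "oh", "o3", "no3")

    def __post_init__(self) -> None:
        for name in self._MONTHLY:
            if name not in self.ds:
                raise ValueError(f"environment missing field {name!r}")
            if tuple(self.ds[name].dims) != ("month", "lat", "lon"):
                raise ValueError(f"{name} must have dims (month, lat, lon)")
            if not np.isfinite(self.ds[name].values).all() or (self.ds[name].values < 0).any():
                raise ValueError(f"{name} must be finite and >= 0")
        if float(self.mixing_height.min()) <= 0:
            raise ValueError("mixing_height must be > 0")

    @property
    def lat(self) -> np.ndarray:
        return self.ds.lat.values

    @property
    def lon(self) -> np.ndarray:
        return self.ds.lon.values

    @property
    def mixing_height(self) -> xr.DataArray:
        return self.ds["mixing_height"]

    @property
    def k_dep_gas(self) -> float:
        return float(self.ds["k_dep_gas"])

    @property
    def k_dep_particle(self) -> float:
        return float(self.ds["k_dep_particle"])

    @property
    def land_mask(self) -> xr.DataArray:
        return self.ds["land_mask"].astype(bool)

    def month(self, m: int) -> xr.Dataset:
        return self.ds[list(self._MONTHLY)].sel(month=m)

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.ds.copy()
        ds["land_mask"] = ds["land_mask"].astype(np.int8)
        ds.attrs.setdefault(
            "grid_convention", "cell-centered regular lat-lon, degrees, latitude ascending"
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "EnvironmentFields":
        with xr.open_dataset(path, engine="scipy") as ds:
            loaded = ds.load()
        return cls(ds=loaded)


def make_environment(
    lat: np.ndarray,
    lon: np.ndarray,
    monthly: dict[str, np.ndarray],
    mixing_height: float | np.ndarray = 1000.0,
    k_dep_gas: float = 1.0e-6,
    k_dep_particle: float = 1.0e-5,
    land_mask: np.ndarray | None = None,
) -> EnvironmentFields:
    """Assemble :class:`EnvironmentFields` from raw (12, nlat, nlon) arrays."""
    coords = {"month": np.arange(1, 13), "lat": np.asarray(lat, float), "lon": np.asarray(lon, float)}
    data = {
        name: xr.DataArray(np.asarray(arr, float), coords=coords, dims=("month", "lat", "lon"))
        for name, arr in monthly.items()
    }
    nlat, nlon = len(coords["lat"]), len(coords["lon"])
    mh = np.broadcast_to(np.asarray(mixing_height, float), (nlat, nlon)).copy()
    data["mixing_height"] = xr.DataArray(
        mh, coords={"lat": coords["lat"], "lon": coords["lon"]}, dims=("lat", "lon"),
        attrs={"units": "m"},
    )
    data["k_dep_gas"] = xr.DataArray(float(k_dep_gas), attrs={"units": "s-1"})
    data["k_dep_particle"] = xr.DataArray(float(k_dep_particle), attrs={"units": "s-1"})
    if land_mask is None:
        land_mask = np.ones((nlat, nlon), dtype=bool)
    data["land_mask"] = xr.DataArray(
        np.asarray(land_mask, bool),
        coords={"lat": coords["lat"], "lon": coords["lon"]},
        dims=("lat", "lon"),
    )
    return EnvironmentFields(ds=xr.Dataset(data))


@dataclass(frozen=True)
class ConcentrationState:
    """Per-species, per-phase gridded concentrations (ng m-3) plus diagnosed
    NPAH/DNPAH fields per parent; ``period`` documents the averaging window."""

    ds: xr.Dataset
    period: str = "instant"

    def __post_init__(self) -> None:
        for name in ("conc", "npah", "dnpah"):
            if name not in self.ds:
                raise ValueError(f"state missing variable {name!r}")
        if tuple(self.ds["conc"].dims) != ("species", "phase", "lat", "lon"):
            raise ValueError("conc must have dims (species, phase, lat, lon)")
        if (self.ds["conc"].values < 0).any():
            raise ValueError("negative concentrations")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.ds.species.values]

    @property
    def conc(self) -> xr.DataArray:
        return self.ds["conc"]

    @property
    def npah(self) -> xr.DataArray:
        return self.ds["npah"]

    @property
    def dnpah(self) -> xr.DataArray:
        return self.ds["dnpah"]

    def total(self) -> xr.DataArray:
        """All-phase concentration per species (ng m-3)."""
        return self.conc.sum(dim="phase")

    def gas(self) -> xr.DataArray:
        return self.conc.sel(phase="gas")

    def particle(self) -> xr.DataArray:
        return self.conc.sel(phase=["particle_oc", "particle_bc"]).sum(dim="phase")

    def to_netcdf(self, path: str | Path, **attrs) -> None:
        ds = self.ds.copy()
        ds["conc"].attrs["units"] = "ng m-3"
        ds.attrs["period"] = self.period
        for k, v in attrs.items():
            ds.attrs[k] = v
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "ConcentrationState":
        with xr.open_dataset(path, engine="scipy") as ds:
            loaded = ds.load()
        return cls(ds=loaded, period=str(loaded.attrs.get("period", "instant")))


def state_from_arrays(
    conc: np.ndarray,
    npah: np.ndarray,
    dnpah: np.ndarray,
    species: list[str],
    lat: np.ndarray,
    lon: np.ndarray,
    period: str = "instant",
) -> ConcentrationState:
    coords = {
        "species": species,
        "phase": list(PHASES),
        "lat": np.asarray(lat, float),
        "lon": np.asarray(lon, float),
    }
    ds = xr.Dataset(
        {
            "conc": (("species", "phase", "lat", "lon"), np.asarray(conc, float)),
            "npah": (("species", "lat", "lon"), np.asarray(npah, float)),
            "dnpah": (("species", "lat", "lon"), np.asarray(dnpah, float)),
        },
        coords=coords,
    )
    return ConcentrationState(ds=ds, period=period)


def zero_state(species: list[str], lat, lon, period: str = "instant") -> ConcentrationState:
    nlat, nlon = len(lat), len(lon)
    ns = len(species)
    return state_from_arrays(
        np.zeros((ns, len(PHASES), nlat, nlon)),
        np.zeros((ns, nlat, nlon)),
        np.zeros((ns, nlat, nlon)),
        species, lat, lon, period,
    )


# ---------------------------------------------------------------------------
# partitioning


def partition_coefficient(
    species: SpeciesDescriptor, temperature, system: PplferSystem | None = None
):
    """Gas-particle partition coefficient Kp (m3 ug-1) from the ppLFER form.

    ``temperature`` may be a scalar or array (K); must lie in 150-350 K.
    """
    system = system or PplferSystem()
    t = np.asarray(temperature, dtype=float)
    if np.any((t < 150.0) | (t > 350.0)):
        raise ValueError("temperature outside physical range 150-350 K")
    if len(species.pplfer) != len(system.coefficients):
        raise ValueError(f"{species.abbreviation}: missing ppLFER descriptors")
    log_kp = (
        system.intercept
        + float(np.dot(system.coefficients, species.pplfer))
        + system.temperature_slope * (1000.0 / t - 1000.0 / T_REF)
    )
    return 10.0**log_kp


def particulate_fraction(kp, c_pm):
    """Equilibrium particle-phase fraction: phi = Kp*PM / (1 + Kp*PM)."""
    kp = np.asarray(kp, dtype=float)
    c_pm = np.asarray(c_pm, dtype=float)
    x = kp * c_pm
    return x / (1.0 + x)


def heterogeneous_loss_rate(gamma_o3, o3_ppb, config: FateConfig | None = None):
    """First-order particle-phase ozonolysis rate (s-1)."""
    config = config or FateConfig()
    return np.asarray(gamma_o3, float) * config.k_het_per_ppb * np.asarray(o3_ppb, float)


# ---------------------------------------------------------------------------
# degradation-product diagnosis


def pyrene_product_ratios(
    oh, no3, registry: SpeciesRegistry, config: FateConfig | None = None
):
    """Local steady-state nitro-PYR:PYR and dinitro-PYR:PYR ratios.

    Sequential first-order nitration of pyrene by NO3 with configurable
    yields, balanced against OH-driven product loss (with a small floor so
    the steady state exists in oxidant-free cells):

        r_n  = yield_n  * k_no3(PYR) * [NO3] / (k_oh_npah  * [OH] + floor)
        r_dn = r_n * yield_dn * k_2nd * [NO3] / (k_oh_dnpah * [OH] + floor)

    Both ratios are non-decreasing in [NO3].
    """
    config = config or FateConfig()
    k_no3_pyr = registry["PYR"].k_no3
    oh = np.asarray(oh, float)
    no3 = np.asarray(no3, float)
    loss_n = config.k_oh_npah * oh + config.k_loss_floor
    loss_dn = config.k_oh_dnpah * oh + config.k_loss_floor
    r_n = config.nitration_yield * k_no3_pyr * no3 / loss_n
    r_dn = r_n * config.dinitration_yield * config.k_second_nitration * no3 / loss_dn
    return r_n, r_dn


def diagnose_degradation_products(
    state: ConcentrationState, pyr_ratio_n, pyr_ratio_dn
) -> ConcentrationState:
    """Fill NPAH/DNPAH fields as product-to-parent ratios times each parent's
    all-phase concentration (the same ratio applied to every parent)."""
    r_n = np.asarray(pyr_ratio_n, float)
    r_dn = np.asarray(pyr_ratio_dn, float)
    if (r_n < 0).any() or (r_dn < 0).any():
        raise ValueError("product-to-parent ratios must be >= 0")
    total = state.total()
    ds = state.ds.copy()
    ds["npah"] = total * r_n
    ds["dnpah"] = total * r_dn
    return ConcentrationState(ds=ds, period=state.period)


# ---------------------------------------------------------------------------
# kinetics


def _kinetic_update(gas, p_oc, p_bc, k_gas, k_particle, emis_rate, dt):
    """Exact solution over ``dt`` of
        d(gas)/dt = emis_rate - k_gas * gas
        d(p)/dt   = -k_particle * p        (each particle reservoir)
    with all rates constant within the step."""
    decay_g = np.exp(-k_gas * dt)
    # -expm1 is accurate for small k*dt; guard the k -> 0 limit with E*dt
    k_safe = np.where(k_gas > 0.0, k_gas, 1.0)
    source = np.where(
        k_gas > 0.0, emis_rate * (-np.expm1(-k_gas * dt)) / k_safe, emis_rate * dt
    )
    decay_p = np.exp(-k_particle * dt)
    return gas * decay_g + source, p_oc * decay_p, p_bc * decay_p


def _equilibrate(total, phi, w_oc, w_bc):
    gas = (1.0 - phi) * total
    return gas, phi * w_oc * total, phi * w_bc * total


def _species_arrays(registry: SpeciesRegistry, species: list[str]):
    """Stack per-species constants into arrays aligned with ``species``."""
    desc = [registry[s] for s in species]
    return {
        "k_oh": np.array([d.k_oh for d in desc]),
        "k_no3": np.array([d.k_no3 for d in desc]),
        "gamma_o3": np.array([d.gamma_o3 for d in desc]),
        "descriptors": np.array([d.pplfer for d in desc]),
    }


def _month_coefficients(
    env_month: xr.Dataset,
    registry: SpeciesRegistry,
    species: list[str],
    config: FateConfig,
    k_dep_gas: float,
    k_dep_particle: float,
):
    """Per-(species, cell) loss rates and equilibrium split for one month."""
    arrs = _species_arrays(registry, species)
    t = env_month["temperature"].values.ravel()[None, :]  # (1, C)
    oh = env_month["oh"].values.ravel()[None, :]
    o3 = env_month["o3"].values.ravel()[None, :]
    no3 = env_month["no3"].values.ravel()[None, :]
    oc = env_month["oc"].values.ravel()
    bc = env_month["bc"].values.ravel()
    c_pm = (oc + bc)[None, :]

    sys = config.pplfer
    solute = arrs["descriptors"] @ np.asarray(sys.coefficients)  # (S,)
    log_kp = (
        sys.intercept
        + solute[:, None]
        + sys.temperature_slope * (1000.0 / t - 1000.0 / T_REF)
    )
    kp = 10.0**log_kp
    phi = particulate_fraction(kp, c_pm)

    pm = oc + bc
    with np.errstate(invalid="ignore", divide="ignore"):
        w_oc = np.where(pm > 0, oc / np.where(pm > 0, pm, 1.0), 0.5)
    w_bc = 1.0 - w_oc

    k_gas = arrs["k_oh"][:, None] * oh + arrs["k_no3"][:, None] * no3 + k_dep_gas
    k_particle = (
        arrs["gamma_o3"][:, None] * config.k_het_per_ppb * o3 + k_dep_particle
    )
    return k_gas, k_particle, phi, w_oc[None, :], w_bc[None, :]


def step_cell(
    state: ConcentrationState,
    env: EnvironmentFields,
    emission_rate: xr.DataArray,
    dt: float,
    registry: SpeciesRegistry,
    config: FateConfig | None = None,
    month: int = 1,
) -> ConcentrationState:
    """Advance a state one time step: exact-exponential kinetic update, then
    instantaneous re-equilibration of the phases.

    ``emission_rate`` is ng m-3 s-1 per (species, lat, lon); emissions enter
    the gas phase. Works on any grid (a single cell being the simplest).
    """
    config = config or FateConfig()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (
        np.array_equal(state.ds.lat.values, env.lat)
        and np.array_equal(state.ds.lon.values, env.lon)
    ):
        raise GridMismatchError("state and environment grids differ")
    conc = state.conc.values
    if (conc < 0).any():
        raise ValueError("negative input concentration")

    species = state.species
    nlat, nlon = conc.shape[2], conc.shape[3]
    ncell = nlat * nlon
    gas = conc[:, 0].reshape(len(species), ncell).copy()
    p_oc = conc[:, 1].reshape(len(species), ncell).copy()
    p_bc = conc[:, 2].reshape(len(species), ncell).copy()
    e_rate = (
        emission_rate.transpose("species", "lat", "lon")
        .values.reshape(len(species), ncell)
    )

    k_gas, k_particle, phi, w_oc, w_bc = _month_coefficients(
        env.month(month), registry, species, config, env.k_dep_gas, env.k_dep_particle
    )
    gas, p_oc, p_bc = _kinetic_update(gas, p_oc, p_bc, k_gas, k_particle, e_rate, dt)
    total = gas + p_oc + p_bc
    gas, p_oc, p_bc = _equilibrate(total, phi, w_oc, w_bc)

    new_conc = np.stack(
        [
            gas.reshape(len(species), nlat, nlon),
            p_oc.reshape(len(species), nlat, nlon),
            p_bc.reshape(len(species), nlat, nlon),
        ],
        axis=1,
    )
    out = state_from_arrays(
        new_conc,
        state.npah.values,
        state.dnpah.values,
        species,
        state.ds.lat.values,
        state.ds.lon.values,
        period="instant",
    )
    return out


def run_scenario(
    inv,
    env: EnvironmentFields,
    registry: SpeciesRegistry,
    config: FateConfig | None = None,
) -> ConcentrationState:
    """Integrate every cell independently over spin-up plus twelve months and
    return the twelve-month (time-weighted) mean state, including diagnosed
    NPAH/DNPAH fields. Deterministic given its inputs."""
    config = config or FateConfig()
    if not (
        np.array_equal(inv.data.lat.values, env.lat)
        and np.array_equal(inv.data.lon.values, env.lon)
    ):
        raise GridMismatchError("inventory and environment grids differ")

    species = inv.species
    for s in species:
        if s not in registry or registry[s].species_class != "parent":
            raise ValueError(f"inventory species {s!r} is not a parent in the registry")

    lat, lon = inv.data.lat.values, inv.data.lon.values
    nlat, nlon = len(lat), len(lon)
    ncell = nlat * nlon
    ns = len(species)

    area = cell_area_m2(lat, lon).values.ravel()
    height = env.mixing_height.values.ravel()
    box_volume = area * height  # m3

    # kg/cell/month summed over sectors -> ng m-3 s-1
    monthly_kg = inv.data.sum(dim="sector").values.reshape(ns, 12, ncell)
    e_rate_by_month = (
        monthly_kg * NG_PER_KG / box_volume[None, None, :] / SECONDS_IN_MONTH[None, :, None]
    )

    gas = np.zeros((ns, ncell))
    p_oc = np.zeros((ns, ncell))
    p_bc = np.zeros((ns, ncell))

    acc = {
        "gas": np.zeros((ns, ncell)),
        "oc": np.zeros((ns, ncell)),
        "bc": np.zeros((ns, ncell)),
        "npah": np.zeros((ns, ncell)),
        "dnpah": np.zeros((ns, ncell)),
    }
    total_seconds = 0.0

    spinup = [((m - 1) % 12) + 1 for m in range(13 - config.spinup_months, 13)]
    schedule = [(m, False) for m in spinup] + [(m, True) for m in range(1, 13)]

    for m, analysis in schedule:
        env_m = env.month(m)
        k_gas, k_particle, phi, w_oc, w_bc = _month_coefficients(
            env_m, registry, species, config, env.k_dep_gas, env.k_dep_particle
        )
        seconds = SECONDS_IN_MONTH[m - 1]
        nsteps = max(1, int(round(seconds / config.dt_seconds)))
        dt = seconds / nsteps
        e_rate = e_rate_by_month[:, m - 1, :]

        decay_g = np.exp(-k_gas * dt)
        k_safe = np.where(k_gas > 0.0, k_gas, 1.0)
        source = np.where(
            k_gas > 0.0, e_rate * (-np.expm1(-k_gas * dt)) / k_safe, e_rate * dt
        )
        decay_p = np.exp(-k_particle * dt)

        month_total = np.zeros((ns, ncell)) if analysis else None
        for _ in range(nsteps):
            gas = gas * decay_g + source
            p_oc = p_oc * decay_p
            p_bc = p_bc * decay_p
            total = gas + p_oc + p_bc
            gas = (1.0 - phi) * total
            p_oc = phi * w_oc * total
            p_bc = phi * w_bc * total
            if analysis:
                acc["gas"] += gas * dt
                acc["oc"] += p_oc * dt
                acc["bc"] += p_bc * dt
                month_total += total * dt

        if analysis:
            r_n, r_dn = pyrene_product_ratios(
                env_m["oh"].values.ravel()[None, :],
                env_m["no3"].values.ravel()[None, :],
                registry,
                config,
            )
            acc["npah"] += r_n * month_total
            acc["dnpah"] += r_dn * month_total
            total_seconds += seconds

    conc = np.stack(
        [
            (acc["gas"] / total_seconds).reshape(ns, nlat, nlon),
            (acc["oc"] / total_seconds).reshape(ns, nlat, nlon),
            (acc["bc"] / total_seconds).reshape(ns, nlat, nlon),
        ],
        axis=1,
    )
    return state_from_arrays(
        conc,
        (acc["npah"] / total_seconds).reshape(ns, nlat, nlon),
        (acc["dnpah"] / total_seconds).reshape(ns, nlat, nlon),
        species,
        lat,
        lon,
        period="annual-mean",
    )


def surface_burden(
    state: ConcentrationState,
    cell_areas: xr.DataArray | None = None,
    mixing_height: xr.DataArray | float = 1000.0,
    registry: SpeciesRegistry | None = None,
) -> dict[str, float]:
    """Surface burden M_i (kg) per species: concentration integrated over
    cell area times mixing height.

    With a ``registry``, burdens of the registry's degradation-product
    species are appended, each drawing on its parent's diagnosed NPAH/DNPAH
    field (split equally among same-class siblings of the same parent).
    """
    if cell_areas is None:
        cell_areas = cell_area_m2(state.ds.lat.values, state.ds.lon.values)
    volume = cell_areas * mixing_height  # (lat, lon) m3
    if float(cell_areas.min()) <= 0 or np.min(np.asarray(mixing_height)) <= 0:
        raise ValueError("areas and mixing heights must be positive")

    burdens: dict[str, float] = {}
    total = state.total()
    for s in state.species:
        burdens[s] = float((total.sel(species=s) * volume).sum()) / NG_PER_KG

    if registry is not None:
        from .health_risk import product_concentrations

        for name, conc in product_concentrations(state, registry).items():
            burdens[name] = float((conc * volume).sum()) / NG_PER_KG
    return burdens
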