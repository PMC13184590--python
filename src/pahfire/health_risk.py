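"""Cancer-risk metrics: gridded incremental lifetime cancer risk (ILCR),
toxicity per unit mass (TPUM), threshold exceedance, and the fire-vs-total
risk decomposition by phase and degradation class.

ILCR per cell is the sum over species of
``unit_risk(BAP) * concentration * TEQ`` with the same TEQ applied to every
phase of a species, so repartitioning mass between phases never changes the
risk. Only species with a known TEQ contribute; others are skipped with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .attribution import area_weighted_mean, difference_state
from .fate_boxmodel import ConcentrationState
from .gridutil import area_weights
from .species_registry import SpeciesRegistry

logger = logging.getLogger(__name__)

#: EPA acceptable-limit benchmark for the ILCR.
ACCEPTABLE_LIMIT = 1.0e-6

#: Unit risk for the reference compound BAP, per (ng m-3).
DEFAULT_UR_A_BAP = 1.0e-6


@dataclass(frozen=True)
class ToxicityTable:
    """Unit risk for BAP plus the TEQ map used in the risk sum."""

    ur_a_bap: float = DEFAULT_UR_A_BAP
    teq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ur_a_bap <= 0:
            raise ValueError("ur_a_bap must be > 0")
        if any(v < 0 for v in self.teq.values()):
            raise ValueError("TEQ values must be >= 0")
        if self.teq and self.teq.get("BAP") != 1.0:
            raise ValueError("teq['BAP'] must be 1 (reference compound)")

    @classmethod
    def from_registry(cls, registry: SpeciesRegistry, ur_a_bap: float = DEFAULT_UR_A_BAP):
        return cls(ur_a_bap=ur_a_bap, teq=registry.teq_map())


@dataclass(frozen=True)
class RiskField:
    """Gridded ILCR with its additive decomposition.

    ``parent_contrib`` has dims (species, phase, lat, lon); ``product_contrib``
    has dims (species, lat, lon) over the degradation-product species. The
    total ``ilcr`` equals the sum of all addends.
    """

    parent_contrib: xr.DataArray
    product_contrib: xr.DataArray
    product_class: dict[str, str]

    @property
    def ilcr(self) -> xr.DataArray:
        return self.parent_contrib.sum(dim=("species", "phase")) + self.product_contrib.sum(
            dim="species"
        )

    def by_phase(self, phases: list[str]) -> xr.DataArray:
        """Parent-species risk summed over the given phases."""
        return self.parent_contrib.sel(phase=phases).sum(dim=("species", "phase"))

    def by_product_class(self, cls_name: str) -> xr.DataArray:
        names = [s for s, c in self.product_class.items() if c == cls_name]
        if not names:
            return xr.zeros_like(self.product_contrib.isel(species=0, drop=True))
        return self.product_contrib.sel(species=names).sum(dim="species")

    def to_netcdf(self, path: str | Path) -> None:
        prod = self.product_contrib.rename(species="species_product")
        ds = xr.Dataset(
            {
                "ilcr": self.ilcr,
                "parent_contrib": self.parent_contrib,
                "product_contrib": prod,
            }
        )
        ds.attrs["product_classes"] = ",".join(
            f"{s}:{c}" for s, c in self.product_class.items()
        )
        ds.to_netcdf(path, engine="scipy")


def product_concentrations(
    state: ConcentrationState, registry: SpeciesRegistry
) -> dict[str, xr.DataArray]:
    """Concentration field (ng m-3) for each registry degradation product.

    Each product draws on its parent's diagnosed class field (npah or
    dnpah); when several same-class products share a parent the parent field
    is split equally among them, so the class total is conserved.
    """
    out: dict[str, xr.DataArray] = {}
    siblings: dict[tuple[str, str], int] = {}
    for prod in registry.products:
        key = (prod.parent, prod.species_class)
        siblings[key] = siblings.get(key, 0) + 1
    for prod in registry.products:
        if prod.parent not in state.species:
            continue
        class_field = state.npah if prod.species_class == "NPAH" else state.dnpah
        share = 1.0 / siblings[(prod.parent, prod.species_class)]
        out[prod.abbreviation] = class_field.sel(species=prod.parent, drop=True) * share
    return out


def compute_ilcr(
    state: ConcentrationState, tox: ToxicityTable, registry: SpeciesRegistry
) -> RiskField:
    """Gridded ILCR = sum over species of UR_A(BAP) * concentration * TEQ.

    Parent species contribute per phase (same TEQ for every phase);
    degradation products contribute through :func:`product_concentrations`.
    Species without a TEQ entry are excluded with a warning.
    """
    if (state.conc.values < 0).any():
        raise ValueError("negative concentration")
    teq_values = []
    for s in state.species:
        if s not in tox.teq:
            logger.warning("species %s has no TEQ; excluded from ILCR", s)
            teq_values.append(0.0)
        else:
            teq_values.append(tox.teq[s])
    teq = xr.DataArray(teq_values, coords={"species": state.species}, dims=("species",))
    parent_contrib = tox.ur_a_bap * state.conc * teq

    prod_fields = product_concentrations(state, registry)
    names, arrays, classes = [], [], {}
    for prod in registry.products:
        if prod.abbreviation not in prod_fields:
            continue
        if prod.abbreviation not in tox.teq:
            logger.warning("product %s has no TEQ; excluded from ILCR", prod.abbreviation)
            continue
        names.append(prod.abbreviation)
        arrays.append(tox.ur_a_bap * prod_fields[prod.abbreviation] * tox.teq[prod.abbreviation])
        classes[prod.abbreviation] = prod.species_class
    if names:
        product_contrib = xr.concat(arrays, dim=pd.Index(names, name="species"))
    else:
        product_contrib = xr.zeros_like(state.npah.isel(species=[0])).assign_coords(
            species=["__none__"]
        )
        classes = {"__none__": "NPAH"}
    return RiskField(
        parent_contrib=parent_contrib, product_contrib=product_contrib, product_class=classes
    )


def compute_tpum(burdens: dict[str, float], tox: ToxicityTable) -> float:
    """Toxicity per unit mass: burden-weighted mean TEQ of a mixture.

    TPUM = sum(M_i * TEQ_i) / sum(M_i); invariant under uniform rescaling of
    the burdens and bounded by the min/max TEQ over species with mass.
    """
    total = sum(burdens.values())
    if total <= 0:
        raise ValueError("zero total burden")
    weighted = 0.0
    for species, mass in burdens.items():
        if species not in tox.teq:
            logger.warning("species %s has no TEQ; excluded from TPUM numerator", species)
            continue
        weighted += mass * tox.teq[species]
    return weighted / total


def exceedance(risk: RiskField, threshold: float = ACCEPTABLE_LIMIT) -> tuple[xr.DataArray, int]:
    """Cells with ILCR strictly above the threshold (boundary cells are not
    counted) and their count."""
    mask = risk.ilcr > threshold
    return mask, int(mask.sum())


def _weighted_sum(field: xr.DataArray) -> float:
    w = area_weights(field.lat.values, field.lon.values)
    return float((field * w).sum())


def risk_decomposition(baseline_risk: RiskField, nowf_risk: RiskField) -> dict[str, float]:
    """Shares (%) of the fire-sourced risk, from per-addend differencing.

    ``gas_share_of_fire`` and ``particle_share_of_fire`` partition the
    fire-sourced parent-species ILCR and sum to 100. ``npah_share`` and
    ``dnpah_share`` are the degradation-product shares of the total
    fire-sourced ILCR (parents + products). ``fire_percent_of_total`` is the
    fire share of the baseline total. All sums are area-weighted and global.
    """
    fire_total = _weighted_sum(baseline_risk.ilcr) - _weighted_sum(nowf_risk.ilcr)
    if fire_total <= 0:
        raise ValueError("zero fire-sourced risk; shares undefined")
    base_total = _weighted_sum(baseline_risk.ilcr)

    fire_gas = _weighted_sum(baseline_risk.by_phase(["gas"])) - _weighted_sum(
        nowf_risk.by_phase(["gas"])
    )
    particle_phases = ["particle_oc", "particle_bc"]
    fire_particle = _weighted_sum(baseline_risk.by_phase(particle_phases)) - _weighted_sum(
        nowf_risk.by_phase(particle_phases)
    )
    fire_parent = fire_gas + fire_particle
    fire_npah = _weighted_sum(baseline_risk.by_product_class("NPAH")) - _weighted_sum(
        nowf_risk.by_product_class("NPAH")
    )
    fire_dnpah = _weighted_sum(baseline_risk.by_product_class("DNPAH")) - _weighted_sum(
        nowf_risk.by_product_class("DNPAH")
    )
    if fire_parent <= 0:
        raise ValueError("zero fire-sourced parent risk; phase shares undefined")
    return {
        "fire_percent_of_total": 100.0 * fire_total / base_total,
        "gas_share_of_fire": 100.0 * fire_gas / fire_parent,
        "particle_share_of_fire": 100.0 * fire_particle / fire_parent,
        "npah_share": 100.0 * fire_npah / fire_total,
        "dnpah_share": 100.0 * fire_dnpah / fire_total,
    }


def tpum_report(
    baseline: ConcentrationState,
    nowf: ConcentrationState,
    registry: SpeciesRegistry,
    tox: ToxicityTable,
    mixing_height: xr.DataArray | float = 1000.0,
) -> dict[str, float]:
    """TPUM for the all-source, non-fire and fire-sourced mixtures."""
    from .fate_boxmodel import surface_burden

    fire = difference_state(baseline, nowf)
    out = {}
    for label, state in (("all_source", baseline), ("non_fire", nowf), ("fire", fire)):
        burdens = surface_burden(
            state, mixing_height=mixing_height, registry=registry
        )
        out[label] = compute_tpum(burdens, tox)
    return out
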