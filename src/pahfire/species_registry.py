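"""Species registry: the 16 priority parent PAHs plus nitro/dinitro
degradation products, with the per-species chemistry and toxicity parameters
used by every downstream stage.

The registry is loaded from a CSV table (one row per species); a default
table ships with the package and every value in it is overridable per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Abbreviations of the 16 priority parent PAHs the registry must contain.
PRIORITY_PARENTS = (
    "NAP", "ACY", "ACE", "FLO", "PHEN", "ANT", "FLA", "PYR",
    "BAA", "CHR", "BBF", "BKF", "BAP", "BGHIP", "ICDP", "DAHA",
)

REFERENCE_SPECIES = "BAP"

VALID_CLASSES = ("parent", "NPAH", "DNPAH")

#: ppLFER descriptor order used throughout (Abraham-style E, S, A, B, L).
PPLFER_DESCRIPTORS = ("e", "s", "a", "b", "l")

_REQUIRED_COLUMNS = (
    "abbreviation", "full_name", "ring_count", "species_class", "parent",
    "molecular_weight", "teq", "k_oh", "k_no3", "gamma_o3",
) + tuple(f"pplfer_{d}" for d in PPLFER_DESCRIPTORS)


class SpeciesTableError(ValueError):
    """Raised when a species table violates a registry invariant."""


@dataclass(frozen=True)
class SpeciesDescriptor:
    """Per-species chemistry and toxicity properties.

    Attributes
    ----------
    abbreviation : short name, e.g. ``"NAP"`` or ``"BAP"``.
    ring_count : number of aromatic rings (2-6 for parents).
    species_class : one of ``"parent"``, ``"NPAH"``, ``"DNPAH"``.
    parent : parent abbreviation for degradation products, else ``None``.
    teq : toxic equivalency relative to BAP (dimensionless, >= 0).
    k_oh, k_no3 : gas-phase rate constants (cm^3 molecule^-1 s^-1).
    gamma_o3 : heterogeneous O3 reactive-uptake parameter (dimensionless).
    pplfer : partitioning descriptors, ordered per :data:`PPLFER_DESCRIPTORS`.
    """

    abbreviation: str
    full_name: str
    ring_count: int
    species_class: str
    molecular_weight: float
    teq: float
    k_oh: float
    k_no3: float
    gamma_o3: float
    pplfer: tuple[float, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.species_class not in VALID_CLASSES:
            raise SpeciesTableError(
                f"{self.abbreviation}: unknown species_class {self.species_class!r}"
            )
        if self.species_class == "parent" and self.ring_count not in (2, 3, 4, 5, 6):
            raise SpeciesTableError(
                f"{self.abbreviation}: parent ring_count must be 2-6, got {self.ring_count}"
            )
        if self.teq < 0:
            raise SpeciesTableError(f"{self.abbreviation}: teq must be >= 0")
        for name, val in (("k_oh", self.k_oh), ("k_no3", self.k_no3), ("gamma_o3", self.gamma_o3)):
            if val < 0:
                raise SpeciesTableError(f"{self.abbreviation}: {name} must be >= 0")
        if len(self.pplfer) != len(PPLFER_DESCRIPTORS):
            raise SpeciesTableError(
                f"{self.abbreviation}: expected {len(PPLFER_DESCRIPTORS)} ppLFER descriptors"
            )


@dataclass
class SpeciesRegistry:
    """Collection of :class:`SpeciesDescriptor` keyed by abbreviation."""

    species: dict[str, SpeciesDescriptor] = field(default_factory=dict)

    def __getitem__(self, abbreviation: str) -> SpeciesDescriptor:
        return self.species[abbreviation]

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self.species

    def __iter__(self):
        return iter(self.species.values())

    def __len__(self) -> int:
        return len(self.species)

    @property
    def parents(self) -> list[SpeciesDescriptor]:
        return [s for s in self if s.species_class == "parent"]

    @property
    def products(self) -> list[SpeciesDescriptor]:
        return [s for s in self if s.species_class in ("NPAH", "DNPAH")]

    def parent_names(self) -> list[str]:
        return [s.abbreviation for s in self.parents]

    def by_ring_count(self, counts: set[int]) -> list[str]:
        """Parent abbreviations with ring_count in ``counts``."""
        return [s.abbreviation for s in self.parents if s.ring_count in counts]

    def teq_map(self) -> dict[str, float]:
        return {s.abbreviation: s.teq for s in self}

    def validate(self) -> None:
        """Check registry-level invariants; raise :class:`SpeciesTableError`."""
        if REFERENCE_SPECIES not in self.species:
            raise SpeciesTableError("reference species absent: registry must contain BAP")
        if self[REFERENCE_SPECIES].teq != 1.0:
            raise SpeciesTableError("BAP must have teq = 1 (reference compound)")
        # the reference compound is unique by definition
        dup_ref = [
            s.abbreviation for s in self
            if s.teq == 1.0 and s.abbreviation != REFERENCE_SPECIES
        ]
        if dup_ref:
            raise SpeciesTableError(f"species other than BAP with teq = 1: {dup_ref}")
        missing = [p for p in PRIORITY_PARENTS if p not in self.species]
        if missing:
            raise SpeciesTableError(f"missing priority parents: {missing}")
        for s in self.products:
            if s.parent is None or s.parent not in self.species:
                raise SpeciesTableError(
                    f"{s.abbreviation}: degradation product needs a parent present in the registry"
                )


def load_species_table(path: str | Path) -> SpeciesRegistry:
    """Load a species registry from a CSV table.

    The table must have a header row and one species per row; lines starting
    with ``#`` are comments. Raises :class:`SpeciesTableError` on duplicate
    abbreviations, negative TEQs, unknown classes, or a missing reference
    species.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SpeciesTableError(f"species table missing columns: {missing_cols}")
    if df["abbreviation"].duplicated().any():
        dups = sorted(df.loc[df["abbreviation"].duplicated(), "abbreviation"])
        raise SpeciesTableError(f"duplicate abbreviation(s): {dups}")

    registry = SpeciesRegistry()
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent")
        if parent is None or (isinstance(parent, float) and math.isnan(parent)) or parent == "":
            parent = None
        desc = SpeciesDescriptor(
            abbreviation=str(row.abbreviation),
            full_name=str(row.full_name),
            ring_count=int(row.ring_count),
            species_class=str(row.species_class),
            parent=parent,
            molecular_weight=float(row.molecular_weight),
            teq=float(row.teq),
            k_oh=float(row.k_oh),
            k_no3=float(row.k_no3),
            gamma_o3=float(row.gamma_o3),
            pplfer=tuple(float(getattr(row, f"pplfer_{d}")) for d in PPLFER_DESCRIPTORS),
        )
        registry.species[desc.abbreviation] = desc
    registry.validate()
    return registry


def write_species_table(registry: SpeciesRegistry, path: str | Path) -> None:
    """Write a registry back to CSV (inverse of :func:`load_species_table`)."""
    rows = []
    for s in registry:
        row = {
            "abbreviation": s.abbreviation,
            "full_name": s.full_name,
            "ring_count": s.ring_count,
            "species_class": s.species_class,
            "parent": s.parent if s.parent is not None else "",
            "molecular_weight": np.float64(s.molecular_weight),
            "teq": np.float64(s.teq),
            "k_oh": np.float64(s.k_oh),
            "k_no3": np.float64(s.k_no3),
            "gamma_o3": np.float64(s.gamma_o3),
        }
        for d, v in zip(PPLFER_DESCRIPTORS, s.pplfer):
            row[f"pplfer_{d}"] = np.float64(v)
        rows.append(row)
    # repr-precision floats so numeric fields round-trip bit-identically
    pd.DataFrame(rows).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def load_default_registry() -> SpeciesRegistry:
    """Registry from the table shipped with the package."""
    from pahfire import default_species_table_path

    return load_species_table(default_species_table_path())


def classify_weight_class(species: SpeciesDescriptor) -> str:
    """Classify a parent PAH as ``"LMW"`` (2-4 rings) or ``"HMW"`` (5-6 rings)."""
    if species.species_class != "parent":
        raise ValueError(f"{species.abbreviation}: weight class applies to parents only")
    if species.ring_count in (2, 3, 4):
        return "LMW"
    if species.ring_count in (5, 6):
        return "HMW"
    raise ValueError(f"{species.abbreviation}: ring_count {species.ring_count} outside 2-6")
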