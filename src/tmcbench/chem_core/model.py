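"""Core molecular data model and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from tmcbench.chem_core.elements import D_BLOCK, group_number

__all__ = [
    "AtomicStructure",
    "PropertyRecord",
    "SpinStatePair",
    "ValidationError",
    "d_electron_count",
]

#: Minimum allowed interatomic distance (Å).
MIN_DISTANCE = 0.3

PROPERTY_UNITS = {
    "delta_e_hs_ls": "kcal/mol",
    "homo": "eV",
    "lumo": "eV",
    "gap": "eV",
    "dipole_mag": "debye",
}


class ValidationError(ValueError):
    """A structure or record violates a model invariant."""


@dataclass
class AtomicStructure:
    """A molecule/complex: elements, Cartesian coordinates (Å), total charge
    (elementary charges) and spin multiplicity (2S+1).

    ``metal_index`` addresses the (single) transition-metal center when known;
    ``tags`` carries free-form string metadata such as ``spin_label`` or
    ``complex_id``.
    """

    id: str
    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    total_charge: int = 0
    multiplicity: int = 1
    metal_index: int | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.total_charge

    def distance_matrix(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))

    # -- validation ---------------------------------------------------------
    def validate(self) -> "AtomicStructure":
        if self.n_atoms == 0:
            raise ValidationError(f"{self.id}: empty structure")
        if np.any(self.atomic_numbers < 1):
            raise ValidationError(f"{self.id}: non-positive atomic number")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(f"{self.id}: non-finite coordinates")
        if self.multiplicity < 1:
            raise ValidationError(f"{self.id}: multiplicity must be >= 1")
        ne = self.n_electrons
        if ne < 1:
            raise ValidationError(f"{self.id}: electron count {ne} < 1")
        n_unpaired = self.multiplicity - 1
        if ne - n_unpaired < 0 or (ne - n_unpaired) % 2 != 0:
            raise ValidationError(
                f"{self.id}: charge {self.total_charge} and multiplicity "
                f"{self.multiplicity} inconsistent with {ne} electrons"
            )
        if self.metal_index is not None:
            if not 0 <= self.metal_index < self.n_atoms:
                raise ValidationError(f"{self.id}: metal_index out of range")
            if int(self.atomic_numbers[self.metal_index]) not in D_BLOCK:
                raise ValidationError(
                    f"{self.id}: metal_index addresses non-d-block atom "
                    f"Z={self.atomic_numbers[self.metal_index]}"
                )
        if self.n_atoms > 1 and pdist(self.coordinates).min() < MIN_DISTANCE:
            raise ValidationError(f"{self.id}: atoms closer than {MIN_DISTANCE} Å")
        return self

    def with_metal_inferred(self) -> "AtomicStructure":
        """Set ``metal_index`` to the unique d-block atom if exactly one exists."""
        if self.metal_index is None:
            hits = [i for i, z in enumerate(self.atomic_numbers) if int(z) in D_BLOCK]
            if len(hits) == 1:
                self.metal_index = hits[0]
        return self


@dataclass(frozen=True)
class PropertyRecord:
    """One labelled property value for one structure."""

    structure_id: str
    property_name: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTY_UNITS:
            raise ValidationError(f"unknown property {self.property_name!r}")
        expected = PROPERTY_UNITS[self.property_name]
        if self.units != expected:
            raise ValidationError(
                f"{self.property_name} must be reported in {expected}, got {self.units}"
            )


@dataclass
class SpinStatePair:
    """Low-spin / high-spin geometry pair with the adiabatic spin-splitting
    energy ΔE(HS−LS) in kcal/mol (positive ⇔ LS lower in energy)."""

    complex_id: str
    ls: AtomicStructure
    hs: AtomicStructure
    delta_e_hs_ls: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.ls.atomic_numbers, self.hs.atomic_numbers):
            raise ValidationError(f"{self.complex_id}: LS/HS element sequences differ")
        if self.hs.multiplicity <= self.ls.multiplicity:
            raise ValidationError(
                f"{self.complex_id}: HS multiplicity must exceed LS multiplicity"
            )


def d_electron_count(structure: AtomicStructure, oxidation_state: int) -> int:
    """d-electron count of the metal center: group number − oxidation state."""
    if structure.metal_index is None:
        raise ValidationError(f"{structure.id}: metal_index not set")
    if not -1 <= oxidation_state <= 4:
        raise ValueError(f"oxidation state {oxidation_state} outside -1..+4")
    z = int(structure.atomic_numbers[structure.metal_index])
    count = group_number(z) - oxidation_state
    if not 0 <= count <= 10:
        raise ValueError(f"d-electron count {count} outside 0..10 for Z={z}")
    return count
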