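"""Monodentate ligand library for the octahedral generator.

Templates place the donor atom at the origin with the ligand body extending
along +z (away from the metal once attached). Field strengths are
dimensionless spectrochemical weights ordered along the usual series
(halides < O-donors < N-donors < CN−/CO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LigandSpec", "DEFAULT_LIGANDS", "ligand_by_name"]


@dataclass(frozen=True)
class LigandSpec:
    name: str
    donor_z: int
    atomic_numbers: tuple[int, ...]
    template: np.ndarray  # (n_atoms, 3), donor first at origin, Å
    formal_charge: int
    field_strength: float
    bond_length_ls: float  # metal–donor distance, Å, generic 3d M(II) reference
    bond_length_hs: float = field(default=0.0)

    def __post_init__(self) -> None:
        tmpl = np.asarray(self.template, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "template", tmpl)
        if self.bond_length_hs == 0.0:
            object.__setattr__(self, "bond_length_hs", self.bond_length_ls + 0.15)
        if not np.allclose(tmpl[0], 0.0):
            raise ValueError(f"{self.name}: donor atom must sit at the template origin")
        if self.bond_length_hs <= self.bond_length_ls:
            raise ValueError(f"{self.name}: HS bond length must exceed LS bond length")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)


def _umbrella(n: int, radial: float, z: float) -> list[list[float]]:
    angles = [2.0 * np.pi * k / n for k in range(n)]
    return [[radial * np.cos(a), radial * np.sin(a), z] for a in angles]


DEFAULT_LIGANDS: tuple[LigandSpec, ...] = (
    LigandSpec(
        name="aqua", donor_z=8, atomic_numbers=(8, 1, 1),
        template=np.array([[0, 0, 0], [0.7572, 0, 0.5865], [-0.7572, 0, 0.5865]]),
        formal_charge=0, field_strength=1.00, bond_length_ls=2.00,
    ),
    LigandSpec(
        name="ammine", donor_z=7, atomic_numbers=(7, 1, 1, 1),
        template=np.array([[0.0, 0.0, 0.0]] + _umbrella(3, 0.94, 0.38)),
        formal_charge=0, field_strength=1.25, bond_length_ls=2.05,
    ),
    LigandSpec(
        name="carbonyl", donor_z=6, atomic_numbers=(6, 8),
        template=np.array([[0, 0, 0], [0, 0, 1.13]]),
        formal_charge=0, field_strength=1.80, bond_length_ls=1.90,
    ),
    LigandSpec(
        name="cyanide", donor_z=6, atomic_numbers=(6, 7),
        template=np.array([[0, 0, 0], [0, 0, 1.16]]),
        formal_charge=-1, field_strength=1.70, bond_length_ls=1.95,
    ),
    LigandSpec(
        name="chloride", donor_z=17, atomic_numbers=(17,),
        template=np.zeros((1, 3)),
        formal_charge=-1, field_strength=0.70, bond_length_ls=2.35,
    ),
    LigandSpec(
        name="fluoride", donor_z=9, atomic_numbers=(9,),
        template=np.zeros((1, 3)),
        formal_charge=-1, field_strength=0.82, bond_length_ls=1.95,
    ),
    # closed-shell CH2=NH stand-in for an unsaturated N-donor
    LigandSpec(
        name="imine", donor_z=7, atomic_numbers=(7, 6, 1, 1, 1),
        template=np.array(
            [
                [0.0, 0.0, 0.0],
                [1.085, 0.0, 0.678],
                [-0.900, 0.0, 0.480],
                [2.045, 0.0, 0.290],
                [1.190, 0.0, 1.752],
            ]
        ),
        formal_charge=0, field_strength=1.35, bond_length_ls=2.05,
    ),
    LigandSpec(
        name="isothiocyanate", donor_z=7, atomic_numbers=(7, 6, 16),
        template=np.array([[0, 0, 0], [0, 0, 1.17], [0, 0, 2.79]]),
        formal_charge=-1, field_strength=0.95, bond_length_ls=2.05,
    ),
)

_BY_NAME = {lig.name: lig for lig in DEFAULT_LIGANDS}


def ligand_by_name(name: str) -> LigandSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown ligand {name!r}") from None
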