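"""Octahedral complex construction and spin-state bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from tmcbench.chem_core import AtomicStructure, element_record, group_number
from tmcbench.synthetic.ligands import LigandSpec

__all__ = [
    "ComplexRecipe",
    "GenerationError",
    "build_octahedral",
    "enumerate_spin_states",
    "vertical_charge_variant",
]

_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
)

#: Reference 3d M(II) covalent radius the ligand bond lengths are calibrated to.
_REFERENCE_METAL_RADIUS = 1.40


class GenerationError(RuntimeError):
    """Structure generation produced a steric clash or invalid geometry."""


@dataclass(frozen=True)
class ComplexRecipe:
    """What a generated complex is made of (the oracle's input)."""

    complex_id: str
    metal_z: int
    oxidation_state: int
    ligand_names: tuple[str, ...]  # six entries, axis order

    @property
    def d_count(self) -> int:
        return group_number(self.metal_z) - self.oxidation_state


def enumerate_spin_states(d_count: int) -> tuple[int, int]:
    """(LS, HS) multiplicities for an octahedral d^n center.

    HS follows maximal octahedral spin (d4→5, d5→6, d6→5, d7→4); LS is the
    minimal parity-consistent multiplicity for d4–d7 and equals HS otherwise.
    """
    if not 0 <= d_count <= 10:
        raise ValueError(f"d-electron count {d_count} outside 0..10")
    hs_table = {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6, 6: 5, 7: 4, 8: 3, 9: 2, 10: 1}
    hs = hs_table[d_count]
    ls = (1 if d_count % 2 == 0 else 2) if 4 <= d_count <= 7 else hs
    return ls, hs


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(u, z):
        return np.eye(3)
    if np.allclose(u, -z):
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, u)
    s, c = np.linalg.norm(v), float(z @ u)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def build_octahedral(
    recipe: ComplexRecipe,
    ligands: tuple[LigandSpec, ...],
    spin_label: str,
) -> AtomicStructure:
    """Place six monodentate ligands at ±x, ±y, ±z around the metal.

    Bond lengths use the ligand's LS or HS reference value, adjusted by the
    metal's covalent radius relative to a generic 3d M(II) and a small
    oxidation-state contraction. Total charge is the oxidation state plus the
    summed ligand formal charges; multiplicity follows
    :func:`enumerate_spin_states`.
    """
    if spin_label not in ("LS", "HS"):
        raise ValueError("spin_label must be 'LS' or 'HS'")
    if len(ligands) != 6:
        raise ValueError("exactly six ligands required")
    metal = element_record(recipe.metal_z)
    radius_shift = metal.covalent_radius - _REFERENCE_METAL_RADIUS
    ox_shift = -0.05 * (recipe.oxidation_state - 2)
    numbers: list[int] = [recipe.metal_z]
    coords: list[np.ndarray] = [np.zeros(3)]
    # fixed per-axis twist about the bond axis keeps bulky cis ligands from
    # colliding while staying fully deterministic
    twists = np.deg2rad([0.0, 60.0, 120.0, 180.0, 240.0, 300.0])
    for axis, lig, twist in zip(_AXES, ligands, twists):
        bond = (lig.bond_length_ls if spin_label == "LS" else lig.bond_length_hs)
        bond += radius_shift + ox_shift
        c, s = np.cos(twist), np.sin(twist)
        twist_z = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rot = _rotation_to(axis) @ twist_z
        placed = bond * axis + lig.template @ rot.T
        numbers.extend(lig.atomic_numbers)
        coords.extend(placed)
    coordinates = np.vstack(coords)
    if len(coordinates) > 1 and pdist(coordinates).min() < 0.3:
        raise GenerationError(f"{recipe.complex_id}: steric clash below 0.3 Å")
    ls, hs = enumerate_spin_states(recipe.d_count)
    total_charge = recipe.oxidation_state + sum(l.formal_charge for l in ligands)
    return AtomicStructure(
        id=f"{recipe.complex_id}_{spin_label}",
        atomic_numbers=np.array(numbers),
        coordinates=coordinates,
        total_charge=total_charge,
        multiplicity=ls if spin_label == "LS" else hs,
        metal_index=0,
        tags={
            "complex_id": recipe.complex_id,
            "spin_label": spin_label,
            "oxidation_state": str(recipe.oxidation_state),
            "ligands": ",".join(recipe.ligand_names),
        },
    )


def vertical_charge_variant(structure: AtomicStructure) -> AtomicStructure:
    """Same geometry, total charge +1, multiplicity nudged ±1 for parity
    (−1 when the multiplicity allows, else +1)."""
    mult = structure.multiplicity - 1 if structure.multiplicity > 1 else structure.multiplicity + 1
    tags = dict(structure.tags)
    if "oxidation_state" in tags:
        tags["oxidation_state"] = str(int(tags["oxidation_state"]) + 1)
    tags["vertical_of"] = structure.id
    return AtomicStructure(
        id=f"{structure.id}_v",
        atomic_numbers=structure.atomic_numbers.copy(),
        coordinates=structure.coordinates.copy(),
        total_charge=structure.total_charge + 1,
        multiplicity=mult,
        metal_index=structure.metal_index,
        tags=tags,
    )
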