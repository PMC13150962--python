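"""Deterministic ligand-field-inspired property oracle.

This is the test harness's ground truth, NOT a physical model from any
reference method: a crystal-field electron-counting expression for the
spin-splitting energy, a charge-shifted frontier-orbital model (cationic
complexes have more stabilized HOMOs), a charge-insensitive gap driven by the
ligand-field splitting, and a formal-charge point-dipole magnitude.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from tmcbench.chem_core import AtomicStructure, PropertyRecord, group_number
from tmcbench.chem_core.elements import atomic_mass
from tmcbench.synthetic.ligands import LigandSpec, ligand_by_name

__all__ = ["OracleParams", "oracle_properties", "noiseless_core"]

_EA_TO_DEBYE = 4.803205  # 1 e·Å in debye

#: (k, m) multipliers for ΔE = k·Δ_oct − m·P by d-electron count.
_SPIN_COEFFS = {4: (1, 1), 5: (2, 2), 6: (2, 2), 7: (1, 1)}


@dataclass(frozen=True)
class OracleParams:
    field_to_splitting: float = 48.0  # kcal/mol per unit mean field strength
    metal_scale_slope: float = 0.05  # per Z away from Fe; charge-independent
    pairing_base: dict = field(
        default_factory=lambda: {24: 44.0, 25: 48.0, 26: 52.0, 27: 52.0, 28: 54.0}
    )
    pairing_default: float = 50.0
    pairing_ox_slope: float = 14.0  # kcal/mol per oxidation-state step
    homo_c0: float = -4.0  # eV
    homo_charge_slope: float = 1.2  # eV per elementary charge, must be > 0
    homo_en_coeff: float = -0.6  # eV per Pauling unit of mean donor EN
    gap_g0: float = 1.2  # eV
    gap_field_coeff: float = 0.045  # eV per kcal/mol of Δ_oct
    noise_sd: dict = field(
        default_factory=lambda: {
            "delta_e_hs_ls": 2.0,
            "homo": 0.15,
            "gap": 0.15,
            "dipole_mag": 0.3,
        }
    )

    def __post_init__(self) -> None:
        if self.homo_charge_slope <= 0:
            raise ValueError("homo_charge_slope must be positive")

    def pairing_energy(self, metal_z: int, oxidation_state: int) -> float:
        base = self.pairing_base.get(metal_z, self.pairing_default)
        return base + self.pairing_ox_slope * (oxidation_state - 2)

    def octahedral_splitting(self, metal_z: int, ligands: list[LigandSpec]) -> float:
        mean_field = float(np.mean([l.field_strength for l in ligands]))
        scale = 1.0 + self.metal_scale_slope * (metal_z - 26)
        return self.field_to_splitting * mean_field * scale


def _noise(seed: int, key: str, sd: float) -> float:
    if sd == 0.0:
        return 0.0
    rng = np.random.default_rng(zlib.crc32(f"{seed}:{key}".encode()))
    return float(rng.normal(0.0, sd))


def noiseless_core(
    metal_z: int,
    oxidation_state: int,
    ligand_names: tuple[str, ...],
    total_charge: int,
    params: OracleParams,
) -> dict[str, float | None]:
    """Noise-free (delta_e, homo, gap) as a pure function of composition.

    ``delta_e_hs_ls`` is None for d-counts without an LS/HS crossover.
    """
    ligands = [ligand_by_name(n) for n in ligand_names]
    d_count = group_number(metal_z) - oxidation_state
    delta_oct = params.octahedral_splitting(metal_z, ligands)
    k, m = _SPIN_COEFFS.get(d_count, (0, 0))
    delta_e = (
        k * delta_oct - m * params.pairing_energy(metal_z, oxidation_state)
        if k else None
    )
    donor_en = float(np.mean([_donor_en(l) for l in ligands]))
    homo = params.homo_c0 - params.homo_charge_slope * total_charge + params.homo_en_coeff * donor_en
    gap = params.gap_g0 + params.gap_field_coeff * delta_oct
    return {"delta_e_hs_ls": delta_e, "homo": homo, "gap": gap}


def _donor_en(lig: LigandSpec) -> float:
    from tmcbench.chem_core import element_record

    return element_record(lig.donor_z).pauling_en


def formal_charge_dipole(structure: AtomicStructure, ligands: list[LigandSpec], oxidation_state: int) -> float:
    """|Σ q_i (r_i − r_com)| in debye, with the metal carrying its oxidation
    state and each ligand's formal charge spread evenly over its atoms."""
    charges = [float(oxidation_state)]
    for lig in ligands:
        charges.extend([lig.formal_charge / lig.n_atoms] * lig.n_atoms)
    q = np.asarray(charges)
    masses = np.array([atomic_mass(int(z)) for z in structure.atomic_numbers])
    com = masses @ structure.coordinates / masses.sum()
    mu = q @ (structure.coordinates - com)
    return float(np.linalg.norm(mu)) * _EA_TO_DEBYE


def oracle_properties(
    structure: AtomicStructure,
    params: OracleParams,
    seed: int = 0,
) -> list[PropertyRecord]:
    """Labels for one generated structure, reading its recipe from tags.

    Noise is seeded per (seed, structure id) — and per (seed, complex id,
    oxidation state) for the pair-level spin splitting so LS and HS members
    share one label — making labels independent of generation order.
    """
    tags = structure.tags
    if "ligands" not in tags or "oxidation_state" not in tags:
        raise ValueError(f"{structure.id}: not generated by this module (missing recipe tags)")
    ligand_names = tuple(tags["ligands"].split(","))
    ox = int(tags["oxidation_state"])
    metal_z = int(structure.atomic_numbers[structure.metal_index])
    core = noiseless_core(metal_z, ox, ligand_names, structure.total_charge, params)
    sd = params.noise_sd
    sid = structure.id
    homo = core["homo"] + _noise(seed, f"homo:{sid}", sd.get("homo", 0.0))
    gap = core["gap"] + _noise(seed, f"gap:{sid}", sd.get("gap", 0.0))
    ligands = [ligand_by_name(n) for n in ligand_names]
    dipole = formal_charge_dipole(structure, ligands, ox)
    dipole = abs(dipole + _noise(seed, f"dip:{sid}", sd.get("dipole_mag", 0.0)))
    records = [
        PropertyRecord(sid, "homo", homo, "eV"),
        PropertyRecord(sid, "lumo", homo + gap, "eV"),
        PropertyRecord(sid, "gap", gap, "eV"),
        PropertyRecord(sid, "dipole_mag", dipole, "debye"),
    ]
    if core["delta_e_hs_ls"] is not None:
        pair_key = f"de:{tags.get('complex_id', sid)}:{ox}"
        de = core["delta_e_hs_ls"] + _noise(seed, pair_key, sd.get("delta_e_hs_ls", 0.0))
        records.append(PropertyRecord(sid, "delta_e_hs_ls", de, "kcal/mol"))
    return records
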