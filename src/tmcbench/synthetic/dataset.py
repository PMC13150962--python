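"""Seeded synthetic dataset generation (structures, labels, LS/HS pairs)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmcbench.chem_core import AtomicStructure, PropertyRecord, SpinStatePair
from tmcbench.synthetic.build import (
    ComplexRecipe,
    build_octahedral,
    enumerate_spin_states,
    vertical_charge_variant,
)
from tmcbench.synthetic.ligands import DEFAULT_LIGANDS, LigandSpec
from tmcbench.synthetic.oracle import OracleParams, oracle_properties

__all__ = ["SyntheticDatasetSpec", "generate_dataset"]

#: Default metal/oxidation-state pool: d4–d8 centers of the 3d row.
DEFAULT_METALS: tuple[tuple[int, int], ...] = (
    (24, 2),  # Cr(II)  d4
    (25, 2),  # Mn(II)  d5
    (25, 3),  # Mn(III) d4
    (26, 2),  # Fe(II)  d6
    (26, 3),  # Fe(III) d5
    (27, 2),  # Co(II)  d7
    (27, 3),  # Co(III) d6
    (28, 2),  # Ni(II)  d8
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_complexes: int = 400
    metals: tuple[tuple[int, int], ...] = DEFAULT_METALS
    ligand_library: tuple[LigandSpec, ...] = DEFAULT_LIGANDS
    seed: int = 0
    oracle: OracleParams = field(default_factory=OracleParams)
    include_vertical_charge_pairs: bool = True
    include_ls_hs_pairs: bool = True

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ConfigurationError("n_complexes must be >= 1")
        if not self.ligand_library:
            raise ConfigurationError("ligand library must not be empty")
        if not self.metals:
            raise ConfigurationError("metal pool must not be empty")


def generate_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[AtomicStructure], list[PropertyRecord], list[SpinStatePair]]:
    """Generate ``spec.n_complexes`` octahedral complexes with labels.

    Deterministic under ``spec.seed``. With LS/HS pairs enabled, both
    geometries share a ``complex_id`` (and the pair's spin-splitting label);
    with vertical pairs enabled, every structure is additionally emitted at
    charge +1 and identical coordinates, with labels recomputed at the new
    oxidation state.
    """
    rng = np.random.default_rng(spec.seed)
    structures: list[AtomicStructure] = []
    labels: list[PropertyRecord] = []
    pairs: list[SpinStatePair] = []

    for i in range(spec.n_complexes):
        metal_z, ox = spec.metals[int(rng.integers(len(spec.metals)))]
        lig_idx = rng.integers(len(spec.ligand_library), size=6)
        ligands = tuple(spec.ligand_library[int(j)] for j in lig_idx)
        recipe = ComplexRecipe(
            complex_id=f"c{i:04d}",
            metal_z=metal_z,
            oxidation_state=ox,
            ligand_names=tuple(l.name for l in ligands),
        )
        ls_mult, hs_mult = enumerate_spin_states(recipe.d_count)
        ls = build_octahedral(recipe, ligands, "LS")
        emitted = [ls]
        if spec.include_ls_hs_pairs and hs_mult > ls_mult:
            hs = build_octahedral(recipe, ligands, "HS")
            emitted.append(hs)
        for s in list(emitted):
            if spec.include_vertical_charge_pairs:
                emitted.append(vertical_charge_variant(s))
        for s in emitted:
            structures.append(s)
            labels.extend(oracle_properties(s, spec.oracle, spec.seed))
        if len(emitted) >= 2 and emitted[1].tags.get("spin_label") == "HS":
            de = next(
                r.value
                for r in labels
                if r.structure_id == ls.id and r.property_name == "delta_e_hs_ls"
            )
            pairs.append(SpinStatePair(recipe.complex_id, ls, emitted[1], de))
    return structures, labels, pairs
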