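"""One-shot extended-Hückel engine: Hamiltonian build, generalized
eigensolution, per-spin occupations/density matrices, spin populations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from tmcbench.chem_core import AtomicStructure, element_record
from tmcbench.guess_electronic.basis import BasisFunction, build_minimal_basis
from tmcbench.guess_electronic.integrals import overlap_matrix

__all__ = [
    "GuessElectronicState",
    "build_hamiltonian",
    "solve_state",
    "spin_population_partition",
]

#: Wolfsberg–Helmholz proportionality constant.
WOLFSBERG_HELMHOLZ_K = 1.75

_CONDITION_LIMIT = 1e10


class BasisTooSmallError(ValueError):
    pass


class IllConditionedOverlapError(ValueError):
    pass


class ClosedShellError(ValueError):
    pass


@dataclass
class GuessElectronicState:
    """Solved one-electron state: matrices, spectrum, occupations, densities.

    Energies are in eV throughout.
    """

    basis: list[BasisFunction]
    S: np.ndarray
    H: np.ndarray
    eigenvalues: np.ndarray  # ascending, eV
    coefficients: np.ndarray  # columns are orbitals, S-orthonormal
    n_alpha: int
    n_beta: int
    D_alpha: np.ndarray
    D_beta: np.ndarray

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    def homo_lumo(self) -> tuple[float, float]:
        """Open-shell convention: HOMO = max over spin channels of the highest
        occupied eigenvalue; LUMO = min over channels of the lowest unoccupied."""
        homo = max(
            self.eigenvalues[n - 1] for n in (self.n_alpha, self.n_beta) if n > 0
        )
        lumo = min(
            self.eigenvalues[n]
            for n in (self.n_alpha, self.n_beta)
            if n < len(self.eigenvalues)
        )
        return float(homo), float(lumo)


def build_hamiltonian(S: np.ndarray, basis: list[BasisFunction]) -> np.ndarray:
    """Wolfsberg–Helmholz Hamiltonian: H_ii from tabulated shell energies,
    H_ij = K * S_ij * (H_ii + H_jj) / 2."""
    h_diag = np.array([bf.ionization_energy_ev for bf in basis])
    mean = 0.5 * (h_diag[:, None] + h_diag[None, :])
    H = WOLFSBERG_HELMHOLZ_K * S * mean
    np.fill_diagonal(H, h_diag)
    return H


def valence_electron_count(structure: AtomicStructure) -> int:
    """Valence electrons held by the engine: Σ n_valence(Z) − total_charge.

    Core shells are absent from the minimal valence basis; their (even)
    electron counts drop out, preserving the charge/multiplicity parity rule.
    """
    n = sum(element_record(int(z)).n_valence_electrons for z in structure.atomic_numbers)
    return n - structure.total_charge


def solve_state(structure: AtomicStructure) -> GuessElectronicState:
    """Build the minimal basis, solve HC = SCε once, and occupy by aufbau.

    The engine carries valence electrons only (the basis has no core
    functions): N_e = Σ n_valence(Z) − total_charge and
    n_alpha = (N_e + multiplicity − 1)/2. Channel densities are built from the
    n_sigma lowest orbitals with stable (index-order) tie-breaking.
    """
    basis = build_minimal_basis(structure)
    S = overlap_matrix(basis, structure.coordinates)
    s_eigs = scipy.linalg.eigvalsh(S)
    if s_eigs[0] <= 0 or s_eigs[-1] / s_eigs[0] > _CONDITION_LIMIT:
        raise IllConditionedOverlapError(
            f"{structure.id}: overlap condition number exceeds {_CONDITION_LIMIT:g}; "
            "check the geometry for near-coincident atoms"
        )
    H = build_hamiltonian(S, basis)
    eigenvalues, C = scipy.linalg.eigh(H, S)

    ne = valence_electron_count(structure)
    n_alpha = (ne + structure.multiplicity - 1) // 2
    n_beta = ne - n_alpha
    if n_beta < 0:
        raise ValueError(
            f"{structure.id}: multiplicity {structure.multiplicity} exceeds "
            f"{ne} valence electrons"
        )
    if n_alpha > len(basis):
        raise BasisTooSmallError(
            f"{structure.id}: {n_alpha} alpha electrons exceed {len(basis)} basis functions"
        )
    D_alpha = C[:, :n_alpha] @ C[:, :n_alpha].T
    D_beta = C[:, :n_beta] @ C[:, :n_beta].T
    return GuessElectronicState(
        basis=basis,
        S=S,
        H=H,
        eigenvalues=eigenvalues,
        coefficients=C,
        n_alpha=n_alpha,
        n_beta=n_beta,
        D_alpha=D_alpha,
        D_beta=D_beta,
    )


def spin_population_partition(
    state: GuessElectronicState,
    structure: AtomicStructure,
    radius: float = 4.5,
) -> tuple[float, float, float]:
    """Mulliken spin-population fractions: (metal, within ``radius`` Å of the
    metal including it, all-ligand). Fractions are relative to the total spin
    n_alpha − n_beta."""
    if structure.metal_index is None:
        raise ValueError(f"{structure.id}: metal_index not set")
    if radius <= 0:
        raise ValueError("radius must be positive")
    total_spin = state.n_alpha - state.n_beta
    if total_spin == 0:
        raise ClosedShellError(f"{structure.id}: closed shell, spin fractions undefined")
    ds = np.diag((state.D_alpha - state.D_beta) @ state.S)
    per_atom = np.zeros(structure.n_atoms)
    for bf, val in zip(state.basis, ds):
        per_atom[bf.atom_index] += val
    metal = structure.metal_index
    dists = np.linalg.norm(structure.coordinates - structure.coordinates[metal], axis=1)
    metal_fraction = per_atom[metal] / total_spin
    within = per_atom[dists <= radius].sum() / total_spin
    ligand_fraction = 1.0 - metal_fraction
    return float(metal_fraction), float(within), float(ligand_fraction)
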