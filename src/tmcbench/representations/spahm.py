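"""Electronically informed fingerprints from the one-electron guess state.

``EigenFeaturizer``: concatenated, zero-padded occupied-orbital eigenvalue
channels (alpha then beta) — global only; charge and spin enter through the
occupation counts. ``DensityFeaturizer``: sorted eigenvalues of the
atom-diagonal blocks of the per-spin density matrices, bagged by element.
"""

from __future__ import annotations

import numpy as np

from tmcbench.chem_core import AtomicStructure, element_record, symbol_of
from tmcbench.representations.base import (
    Featurizer,
    LayoutError,
    UnsupportedVariantError,
    get_state,
)

__all__ = ["EigenFeaturizer", "DensityFeaturizer"]


class EigenFeaturizer(Featurizer):
    """Occupied-spectrum representation; zero-padding is safe because all
    occupied guess eigenvalues are negative."""

    rep_name = "eigen"

    def _finalize_fit(self, structures) -> None:
        counts = [(get_state(s).n_alpha, get_state(s).n_beta) for s in structures]
        self.pad_alpha = max(c[0] for c in counts)
        self.pad_beta = max(c[1] for c in counts)

    def _extra_state(self):
        return (self.pad_alpha, self.pad_beta)

    def _build_layout(self):
        return [("alpha", 0, self.pad_alpha), ("beta", self.pad_alpha, self.pad_beta)]

    def transform(self, structure: AtomicStructure, variant: str = "global"):
        if variant != "global":
            raise UnsupportedVariantError(
                "only the global variant exists for the eigenvalue representation"
            )
        return super().transform(structure, variant)

    def _transform(self, structure: AtomicStructure, variant: str) -> np.ndarray:
        state = get_state(structure)
        if state.n_alpha > self.pad_alpha or state.n_beta > self.pad_beta:
            raise LayoutError(
                f"{structure.id}: occupied counts ({state.n_alpha},{state.n_beta}) "
                f"exceed fitted pad lengths ({self.pad_alpha},{self.pad_beta})"
            )
        vec = np.zeros(self.pad_alpha + self.pad_beta)
        vec[: state.n_alpha] = state.eigenvalues[: state.n_alpha]
        vec[self.pad_alpha : self.pad_alpha + state.n_beta] = state.eigenvalues[: state.n_beta]
        return vec


class DensityFeaturizer(Featurizer):
    """Atom-block density-matrix eigenvalue fingerprints.

    Local variant: the metal atom's block only (its element bag). Global:
    per-element sums of the per-atom fingerprints, concatenated by element.
    """

    rep_name = "density"

    def _finalize_fit(self, structures) -> None:
        self.block_sizes = {
            z: sum(2 * {"s": 0, "p": 1, "d": 2}[shell[1]] + 1 for shell in
                   (sh[0] for sh in element_record(z).eh_shells))
            for z in self.elements
        }

    def _extra_state(self):
        return tuple(sorted(self.block_sizes.items()))

    def _build_layout(self):
        layout, offset = [], 0
        for z in self.elements:
            length = 2 * self.block_sizes[z]  # alpha block then beta block
            layout.append((f"atom:{symbol_of(z)}", offset, length))
            offset += length
        return layout

    @staticmethod
    def _smoothed_density(state, n_occ: int, tol: float = 1e-6) -> np.ndarray:
        """Density with the degenerate boundary group fractionally occupied.

        Aufbau truncation inside a degenerate set picks an arbitrary basis of
        that set, which breaks rotation invariance of the fingerprint (common
        for partially filled d shells of symmetric complexes). Sharing the
        residual occupancy equally over the degenerate group restores it; the
        engine's idempotent integer-occupation densities are left untouched.
        """
        if n_occ == 0:
            return np.zeros_like(state.D_alpha)
        C, eps = state.coefficients, state.eigenvalues
        boundary = eps[n_occ - 1]
        group = np.where(np.abs(eps - boundary) <= tol)[0]
        below = np.where(eps < boundary - tol)[0]
        frac = (n_occ - len(below)) / len(group)
        occ = np.zeros(len(eps))
        occ[below] = 1.0
        occ[group] = frac
        return (C * occ[None, :]) @ C.T

    def _atom_fingerprint(self, state, atom_index: int, z: int) -> np.ndarray:
        idx = [k for k, bf in enumerate(state.basis) if bf.atom_index == atom_index]
        halves = []
        for n_occ in (state.n_alpha, state.n_beta):
            D = self._smoothed_density(state, n_occ)
            block = D[np.ix_(idx, idx)]
            block = 0.5 * (block + block.T)
            halves.append(np.sort(np.linalg.eigvalsh(block)))
        size = self.block_sizes[z]
        out = np.zeros(2 * size)
        out[: len(halves[0])] = halves[0]
        out[size : size + len(halves[1])] = halves[1]
        return out

    def _transform(self, structure: AtomicStructure, variant: str) -> np.ndarray:
        state = get_state(structure)
        vec = np.zeros(self.n_features)
        offsets = {name.split(":", 1)[1]: (off, length) for name, off, length in self.layout}
        atoms = (
            [structure.metal_index]
            if variant == "local"
            else range(structure.n_atoms)
        )
        for i in atoms:
            z = int(structure.atomic_numbers[i])
            off, length = offsets[symbol_of(z)]
            vec[off : off + length] += self._atom_fingerprint(state, i, z)
        return vec
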