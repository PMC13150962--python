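"""Bagged many-body spectral representation (one-, two-, three-body).

Bags are element-resolved: one-body per element (count-weighted nuclear
charge), two-body per unordered element pair (London-style r⁻⁶-weighted
Gaussian spectrum on a radial grid), three-body per unordered element triple
(Axilrod–Teller–Muto-weighted Gaussian spectrum on an angle grid, the angle
taken at the contribution's central atom). The local variant keeps only
spectra in which the metal atom participates, centered at the metal.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement

import numpy as np

from tmcbench.chem_core import AtomicStructure, symbol_of
from tmcbench.representations.base import Featurizer, FeaturizerParams

__all__ = ["SLATMFeaturizer"]


def _gauss(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2) / (width * np.sqrt(2 * np.pi))


class SLATMFeaturizer(Featurizer):
    rep_name = "slatm"

    def _finalize_fit(self, structures) -> None:
        p = self.params
        self.r_grid = np.arange(p.slatm_r_min, p.slatm_r_cut + 0.5 * p.slatm_r_step, p.slatm_r_step)
        self.angle_grid = np.arange(0.0, np.pi + 0.5 * p.slatm_angle_step, p.slatm_angle_step)

    def _build_layout(self):
        layout, offset = [], 0
        for z in self.elements:
            layout.append((f"1b:{symbol_of(z)}", offset, 1))
            offset += 1
        for a, b in combinations_with_replacement(self.elements, 2):
            layout.append((f"2b:{symbol_of(a)}-{symbol_of(b)}", offset, len(self.r_grid)))
            offset += len(self.r_grid)
        for triple in combinations_with_replacement(self.elements, 3):
            name = "3b:" + "-".join(symbol_of(z) for z in triple)
            layout.append((name, offset, len(self.angle_grid)))
            offset += len(self.angle_grid)
        return layout

    def _bag_index(self) -> dict[str, tuple[int, int]]:
        return {name: (off, length) for name, off, length in self.layout}

    def _transform(self, structure: AtomicStructure, variant: str) -> np.ndarray:
        p = self.params
        z = structure.atomic_numbers
        n = structure.n_atoms
        dist = structure.distance_matrix()
        vec = np.zeros(self.n_features)
        index = self._bag_index()
        metal = structure.metal_index

        # one-body
        if variant == "global":
            for zi in z:
                vec[index[f"1b:{symbol_of(int(zi))}"][0]] += float(zi)
        else:
            vec[index[f"1b:{symbol_of(int(z[metal]))}"][0]] += float(z[metal])

        # contributions are collected first and accumulated in a canonical
        # (bag, center, weight) order so global vectors are bitwise invariant
        # under atom-order permutation
        two_body: list[tuple[str, float, float]] = []
        if variant == "global":
            pair_iter = combinations(range(n), 2)
        else:
            pair_iter = ((metal, j) for j in range(n) if j != metal)
        for i, j in pair_iter:
            r = dist[i, j]
            if r > p.slatm_r_cut:
                continue
            a, b = sorted((int(z[i]), int(z[j])))
            weight = 0.5 * z[i] * z[j] / r**6
            two_body.append((f"2b:{symbol_of(a)}-{symbol_of(b)}", r, weight))
        for name, r, weight in sorted(two_body):
            off, length = index[name]
            vec[off : off + length] += weight * _gauss(self.r_grid, r, p.slatm_width)

        # three-body: central atom c with neighbor pair (j, k) within cutoff
        three_body: list[tuple[str, float, float]] = []
        centers = range(n) if variant == "global" else [metal]
        for c in centers:
            neighbors = [j for j in range(n) if j != c and dist[c, j] <= p.slatm_r_cut]
            for j, k in combinations(neighbors, 2):
                # canonical neighbor order keeps float products bitwise
                # permutation-invariant (multiplication is not associative)
                if (z[j], dist[c, j]) > (z[k], dist[c, k]):
                    j, k = k, j
                r_cj, r_ck, r_jk = dist[c, j], dist[c, k], dist[j, k]
                cos_c = _cos_angle(structure.coordinates, c, j, k)
                cos_j = _cos_angle(structure.coordinates, j, c, k)
                cos_k = _cos_angle(structure.coordinates, k, c, j)
                if (z[j], r_cj) == (z[k], r_ck) and cos_j > cos_k:
                    cos_j, cos_k = cos_k, cos_j
                weight = (
                    z[c] * z[j] * z[k]
                    * (1.0 + cos_c * cos_j * cos_k)
                    / (r_cj * r_ck * r_jk) ** 3
                )
                triple = tuple(sorted((int(z[c]), int(z[j]), int(z[k]))))
                name = "3b:" + "-".join(symbol_of(t) for t in triple)
                theta = np.arccos(np.clip(cos_c, -1.0, 1.0))
                three_body.append((name, theta, weight))
        for name, theta, weight in sorted(three_body):
            off, length = index[name]
            vec[off : off + length] += weight * _gauss(self.angle_grid, theta, p.slatm_angle_width)
        return vec


def _cos_angle(coords: np.ndarray, apex: int, i: int, j: int) -> float:
    u = coords[i] - coords[apex]
    v = coords[j] - coords[apex]
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
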