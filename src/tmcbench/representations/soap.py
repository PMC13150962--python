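"""Power spectrum of Gaussian-smeared neighbor densities.

Per center and per element channel, the neighbor density (self excluded) is
expanded onto an orthonormalized Gaussian radial basis × real spherical
harmonics; the rotation-invariant power spectrum p_{nn'l}^{ZZ'} is the
m-contraction of the expansion coefficients. Local variant: metal-centered
spectrum only; global: sum over all centers.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from scipy.special import spherical_in

from tmcbench.chem_core import AtomicStructure, symbol_of
from tmcbench.representations.base import Featurizer

__all__ = ["SOAPFeaturizer", "real_sph_harm", "radial_basis_matrix"]

_SQPI = np.sqrt(np.pi)


def real_sph_harm(l_max: int, unit: np.ndarray) -> list[np.ndarray]:
    """Real spherical harmonics S_lm evaluated at unit vectors.

    ``unit``: (..., 3). Returns one (..., 2l+1) array per l, m ordered
    −l..l. Hand-coded through l = 3.
    """
    x, y, z = unit[..., 0], unit[..., 1], unit[..., 2]
    out = [np.full(x.shape + (1,), 0.28209479177387814)]
    if l_max >= 1:
        c = 0.4886025119029199
        out.append(np.stack([c * y, c * z, c * x], axis=-1))
    if l_max >= 2:
        c1, c2, c3 = 1.0925484305920792, 0.31539156525252005, 0.5462742152960396
        out.append(
            np.stack(
                [c1 * x * y, c1 * y * z, c2 * (3 * z**2 - 1), c1 * x * z, c3 * (x**2 - y**2)],
                axis=-1,
            )
        )
    if l_max >= 3:
        d1 = 0.5900435899266435   # 1/4 sqrt(35/2pi)
        d2 = 2.890611442640554    # 1/2 sqrt(105/pi)
        d3 = 0.4570457994644658   # 1/4 sqrt(21/2pi)
        d4 = 0.3731763325901154   # 1/4 sqrt(7/pi)
        d5 = 1.445305721320277    # 1/4 sqrt(105/pi)
        out.append(
            np.stack(
                [
                    d1 * y * (3 * x**2 - y**2),
                    d2 * x * y * z,
                    d3 * y * (5 * z**2 - 1),
                    d4 * z * (5 * z**2 - 3),
                    d3 * x * (5 * z**2 - 1),
                    d5 * z * (x**2 - y**2),
                    d1 * x * (x**2 - 3 * y**2),
                ],
                axis=-1,
            )
        )
    if l_max >= 4:
        raise NotImplementedError("l_max > 3 not implemented")
    return out


def radial_basis_matrix(n_max: int, r_cut: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian radial shells exp(−b_n r²) with widths spanning the cutoff,
    plus the inverse-square-root overlap that orthonormalizes them.

    Returns (b, W) with g̃_n(r) = Σ_k W[n, k] exp(−b_k r²).
    """
    widths = r_cut * (np.arange(1, n_max + 1)) / (2.0 * n_max)
    b = 1.0 / (2.0 * widths**2)
    overlap = _SQPI / (4.0 * (b[:, None] + b[None, :]) ** 1.5)
    evals, evecs = np.linalg.eigh(overlap)
    W = (evecs / np.sqrt(evals)) @ evecs.T
    return b, W


class SOAPFeaturizer(Featurizer):
    rep_name = "soap"

    def _finalize_fit(self, structures) -> None:
        p = self.params
        self.b, self.W = radial_basis_matrix(p.soap_n_max, p.soap_r_cut)
        self.alpha = 1.0 / (2.0 * p.soap_sigma**2)
        # radial quadrature nodes (Gauss–Legendre) covering the density support
        upper = p.soap_r_cut + 5.0 * p.soap_sigma
        x, w = np.polynomial.legendre.leggauss(200)
        self.quad_r = 0.5 * upper * (x + 1.0)
        self.quad_w = 0.5 * upper * w
        # orthonormal radial basis evaluated on the quadrature grid
        raw = np.exp(-self.b[None, :] * self.quad_r[:, None] ** 2)
        self.basis_on_grid = raw @ self.W.T  # (n_quad, n_max)

    def _build_layout(self):
        p = self.params
        layout, offset = [], 0
        self._channels = []
        for za, zb in combinations_with_replacement(self.elements, 2):
            if za == zb:
                nn = [(i, j) for i in range(p.soap_n_max) for j in range(i, p.soap_n_max)]
            else:
                nn = [(i, j) for i in range(p.soap_n_max) for j in range(p.soap_n_max)]
            length = len(nn) * (p.soap_l_max + 1)
            self._channels.append((za, zb, nn))
            layout.append((f"p:{symbol_of(za)}-{symbol_of(zb)}", offset, length))
            offset += length
        return layout

    def expansion_coefficients(
        self, structure: AtomicStructure, center: int
    ) -> dict[int, list[np.ndarray]]:
        """c_nlm per element channel for one center: {Z: [c[n, m] per l]}."""
        p = self.params
        coords = structure.coordinates
        rel = coords - coords[center]
        dists = np.linalg.norm(rel, axis=1)
        mask = (dists <= p.soap_r_cut) & (np.arange(structure.n_atoms) != center)
        out: dict[int, list[np.ndarray]] = {
            int(z): [np.zeros((p.soap_n_max, 2 * l + 1)) for l in range(p.soap_l_max + 1)]
            for z in self.elements
        }
        if not mask.any():
            return out
        neigh_rel = rel[mask]
        neigh_d = dists[mask]
        neigh_z = structure.atomic_numbers[mask]
        # canonical neighbor order (element, then relative position) keeps the
        # coefficient sums bitwise invariant under atom-order permutation
        order = np.lexsort((neigh_rel[:, 2], neigh_rel[:, 1], neigh_rel[:, 0], neigh_z))
        neigh_rel, neigh_d, neigh_z = neigh_rel[order], neigh_d[order], neigh_z[order]
        harmonics = real_sph_harm(p.soap_l_max, neigh_rel / neigh_d[:, None])
        r, w = self.quad_r, self.quad_w
        # radial integrals I[l, neighbor, n] = ∫ r² g̃_n e^{-αr²} i_l(2αrR) dr
        gauss = np.exp(-self.alpha * r[None, :] ** 2) * r[None, :] ** 2  # (1, nq)
        for li in range(p.soap_l_max + 1):
            bess = spherical_in(li, 2.0 * self.alpha * np.outer(neigh_d, r))  # (nn, nq)
            integrand = bess * gauss  # (nn, nq)
            radial = (integrand * w[None, :]) @ self.basis_on_grid  # (nn, n_max)
            pref = 4.0 * np.pi * np.exp(-self.alpha * neigh_d**2)  # (nn,)
            contrib = radial * pref[:, None]  # (nn, n_max)
            for zi in np.unique(neigh_z):
                sel = neigh_z == zi
                # c[n, m] = Σ_neighbors contrib[i, n] * S_lm[i, m]
                out[int(zi)][li] += contrib[sel].T @ harmonics[li][sel]
        return out

    def power_spectrum(self, coeffs: dict[int, list[np.ndarray]]) -> np.ndarray:
        vec = []
        for za, zb, nn in self._channels:
            ca, cb = coeffs[za], coeffs[zb]
            for li in range(self.params.soap_l_max + 1):
                prods = ca[li] @ cb[li].T  # (n_max, n_max), summed over m
                vec.extend(prods[i, j] for i, j in nn)
        return np.asarray(vec)

    def _transform(self, structure: AtomicStructure, variant: str) -> np.ndarray:
        if variant == "local":
            return self.power_spectrum(
                self.expansion_coefficients(structure, structure.metal_index)
            )
        total = np.zeros(self.n_features)
        c = structure.coordinates
        canonical = np.lexsort((c[:, 2], c[:, 1], c[:, 0], structure.atomic_numbers))
        for center in canonical:
            total += self.power_spectrum(self.expansion_coefficients(structure, int(center)))
        return total
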