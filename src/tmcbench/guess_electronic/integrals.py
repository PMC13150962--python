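"""Analytic overlap integrals for contracted solid-harmonic Gaussians.

Cartesian primitive overlaps come from the Gaussian product theorem with the
standard two-index Hermite recursion in each axis; Cartesian blocks are then
projected onto real solid harmonics (pure d functions) and every contracted
function is normalized to unit self-overlap.
"""

from __future__ import annotations

import numpy as np

from tmcbench.guess_electronic.basis import BasisFunction

__all__ = ["overlap_matrix"]

_CART = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

_SQ3 = np.sqrt(3.0)
# rows: xy, yz, z2, xz, x2-y2 over cart columns xx,xy,xz,yy,yz,zz
_T = {
    0: np.array([[1.0]]),
    1: np.eye(3),
    2: np.array(
        [
            [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
            [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],
            [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],
            [_SQ3 / 2, 0.0, 0.0, -_SQ3 / 2, 0.0, 0.0],
        ]
    ),
}

_ANGSTROM_TO_BOHR = 1.0 / 0.529177210903


def _hermite_1d(pa: np.ndarray, pb: np.ndarray, p: np.ndarray, lmax: int) -> list[list[np.ndarray]]:
    """Table E[i][j] of 1D overlap factors for powers i, j <= lmax."""
    inv2p = 0.5 / p
    E: list[list[np.ndarray | None]] = [[None] * (lmax + 1) for _ in range(lmax + 1)]
    E[0][0] = np.ones_like(p)
    for i in range(lmax + 1):
        for j in range(lmax + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                term = pa * E[i - 1][0]
                if i >= 2:
                    term = term + (i - 1) * inv2p * E[i - 2][0]
                E[i][0] = term
            else:
                term = pb * E[i][j - 1]
                if i >= 1:
                    term = term + i * inv2p * E[i - 1][j - 1]
                if j >= 2:
                    term = term + (j - 1) * inv2p * E[i][j - 2]
                E[i][j] = term
    return E  # type: ignore[return-value]


def _shell_groups(basis: list[BasisFunction]) -> list[tuple[int, int, int]]:
    """Consecutive (start, l, atom_index) runs sharing one shell."""
    groups = []
    i = 0
    while i < len(basis):
        bf = basis[i]
        groups.append((i, bf.l, bf.atom_index))
        i += 2 * bf.l + 1
    return groups


def overlap_matrix(basis: list[BasisFunction], coordinates: np.ndarray) -> np.ndarray:
    """Symmetric overlap matrix with exactly unit diagonal.

    ``coordinates`` are in Å; integrals are evaluated in bohr (the Slater
    exponents are atomic-unit exponents).
    """
    coords = np.asarray(coordinates, dtype=float) * _ANGSTROM_TO_BOHR
    n = len(basis)
    raw = np.zeros((n, n))
    groups = _shell_groups(basis)
    for gi, (ia, la, atom_a) in enumerate(groups):
        bfa = basis[ia]
        A = coords[atom_a]
        wa, aa = bfa.coefficients, bfa.exponents
        for ib, lb, atom_b in groups[gi:]:
            bfb = basis[ib]
            B = coords[atom_b]
            wb, ab = bfb.coefficients, bfb.exponents
            p = aa[:, None] + ab[None, :]
            mu = aa[:, None] * ab[None, :] / p
            AB = A - B
            pref = (np.pi / p) ** 1.5 * np.exp(-mu * float(AB @ AB))
            P = (aa[:, None, None] * A[None, None, :] + ab[None, :, None] * B[None, None, :]) / p[:, :, None]
            lmax = max(la, lb)
            Etabs = [
                _hermite_1d(P[:, :, ax] - A[ax], P[:, :, ax] - B[ax], p, lmax)
                for ax in range(3)
            ]
            carta, cartb = _CART[la], _CART[lb]
            block = np.empty((len(carta), len(cartb)))
            weight = wa[:, None] * wb[None, :] * pref
            for ca, (ax_i, ay_i, az_i) in enumerate(carta):
                for cb, (bx_j, by_j, bz_j) in enumerate(cartb):
                    prod = (
                        Etabs[0][ax_i][bx_j]
                        * Etabs[1][ay_i][by_j]
                        * Etabs[2][az_i][bz_j]
                    )
                    block[ca, cb] = float(np.sum(weight * prod))
            sph = _T[la] @ block @ _T[lb].T
            na, nb = 2 * la + 1, 2 * lb + 1
            raw[ia : ia + na, ib : ib + nb] = sph
            if ia != ib:
                raw[ib : ib + nb, ia : ia + na] = sph.T
    norm = 1.0 / np.sqrt(np.diag(raw))
    S = raw * norm[:, None] * norm[None, :]
    return 0.5 * (S + S.T)
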