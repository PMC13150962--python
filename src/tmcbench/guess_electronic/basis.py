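"""Minimal valence basis: Slater orbitals expanded in contracted Gaussians.

Each valence shell of an element carries a tabulated Slater exponent; the
radial Slater function is fitted once (at zeta = 1) by ``n_gauss`` Gaussians of
matching angular momentum, and the fit is rescaled analytically to any zeta
(exponents scale as zeta**2). Fits are cached per (n, l).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gamma

from tmcbench.chem_core import AtomicStructure, element_record

__all__ = ["BasisFunction", "build_minimal_basis", "fit_slater_gaussians"]

_ANGULAR = {"s": 0, "p": 1, "d": 2}
#: Real-solid-harmonic component labels per angular momentum.
_M_LABELS = {0: ("",), 1: ("x", "y", "z"), 2: ("xy", "yz", "z2", "xz", "x2-y2")}


class UnsupportedElementError(ValueError):
    """Element lacks valence-shell parameters."""


@dataclass(frozen=True)
class BasisFunction:
    """One contracted real-solid-harmonic Gaussian on one atom.

    ``coefficients`` weight radially *normalized* primitives
    ``r**l * exp(-a r**2)``; the contraction itself is normalized so that the
    self-overlap is 1.
    """

    atom_index: int
    shell: str  # e.g. "3d"
    l: int
    m: int  # component index into the real-harmonic ordering
    exponents: np.ndarray
    coefficients: np.ndarray
    ionization_energy_ev: float

    @property
    def label(self) -> str:
        suffix = _M_LABELS[self.l][self.m]
        return f"{self.shell}{suffix}" if suffix else self.shell


def _radial_norm(alpha: np.ndarray, l: int) -> np.ndarray:
    """1/sqrt(<g|g>) for g = r**l exp(-alpha r**2) under the r**2 dr measure."""
    return np.sqrt((2.0 * (2.0 * alpha) ** (l + 1.5)) / gamma(l + 1.5))


def _slater_radial(r: np.ndarray, n: int) -> np.ndarray:
    norm = (2.0) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))
    return norm * r ** (n - 1) * np.exp(-r)


@lru_cache(maxsize=None)
def fit_slater_gaussians(n: int, l: int, n_gauss: int = 3) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Least-squares fit of the unit-exponent Slater radial R_nl to
    ``n_gauss`` normalized Gaussians of angular momentum ``l``.

    Returns (exponents, coefficients) for zeta = 1. Deterministic.
    """
    # radial quadrature grid (log-dense near origin, generous tail)
    x, w = np.polynomial.legendre.leggauss(200)
    r = 0.5 * 40.0 * (x + 1.0)
    wr = 0.5 * 40.0 * w * r * r
    target = _slater_radial(r, n)

    def design(log_alpha: np.ndarray) -> np.ndarray:
        alpha = np.exp(log_alpha)
        g = r[:, None] ** l * np.exp(-alpha[None, :] * r[:, None] ** 2)
        return g * _radial_norm(alpha, l)[None, :]

    def objective(log_alpha: np.ndarray) -> float:
        G = design(log_alpha)
        A = G.T @ (G * wr[:, None])
        b = G.T @ (target * wr)
        try:
            c = np.linalg.solve(A + 1e-12 * np.eye(len(b)), b)
        except np.linalg.LinAlgError:
            return 1e6
        resid = target - G @ c
        return float(resid @ (resid * wr))

    # spread of starting exponents keyed to the Slater principal number
    base = np.geomspace(0.05, 10.0, n_gauss) * (1.0 / n)
    best = None
    for scale in (0.5, 1.0, 2.0):
        res = minimize(objective, np.log(base * scale), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    alpha = np.exp(best.x)
    G = design(best.x)
    A = G.T @ (G * wr[:, None])
    b = G.T @ (target * wr)
    c = np.linalg.solve(A + 1e-12 * np.eye(len(b)), b)
    order = np.argsort(-alpha)
    return tuple(alpha[order]), tuple(c[order])


def shell_primitives(n: int, l: int, zeta: float, n_gauss: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Exponents and contraction weights for a Slater shell with exponent zeta.

    Weights multiply *unnormalized* polynomial Gaussians; the overall scale is
    arbitrary (contractions are renormalized against the analytic self-overlap
    downstream).
    """
    alpha1, c1 = fit_slater_gaussians(n, l, n_gauss)
    alpha = np.asarray(alpha1) * zeta**2
    weights = np.asarray(c1) * _radial_norm(alpha, l)
    return alpha, weights


def build_minimal_basis(structure: AtomicStructure) -> list[BasisFunction]:
    """Valence-only minimal basis, ordered by (atom index, shell, m)."""
    basis: list[BasisFunction] = []
    for atom_index, z in enumerate(structure.atomic_numbers):
        try:
            record = element_record(int(z))
        except ValueError as exc:
            raise UnsupportedElementError(f"no basis parameters for Z={int(z)}") from exc
        for shell, energy, zeta in record.eh_shells:
            n, lsym = int(shell[0]), shell[1]
            l = _ANGULAR[lsym]
            alpha, weights = shell_primitives(n, l, zeta)
            for m in range(2 * l + 1):
                basis.append(
                    BasisFunction(
                        atom_index=atom_index,
                        shell=shell,
                        l=l,
                        m=m,
                        exponents=alpha,
                        coefficients=weights,
                        ionization_energy_ev=energy,
                    )
                )
    return basis
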