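"""Kernel ridge regression with nested cross-validated hyperparameter search.

Kernels: Laplacian k = exp(−‖x−x'‖₁/σ) (default) and Gaussian
k = exp(−‖x−x'‖₂²/2σ²). The width grid σ = 10^(n_σ/2) starts on
n_σ ∈ 0..12 and extends adaptively when the optimum sits on the boundary;
the ridge grid is λ = 10^(−n_λ), n_λ ∈ 0..4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "KRRHyperGrid",
    "KernelModel",
    "kernel_matrix",
    "kernel_from_distance",
    "pairwise_distance",
    "krr_fit",
    "select_hyperparameters",
    "fit_krr_model",
]

_TIE_TOL = 1e-6


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "laplacian"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("laplacian", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class KRRHyperGrid:
    n_lambda: tuple[int, ...] = tuple(range(0, 5))
    n_sigma_start: tuple[int, ...] = tuple(range(0, 13))
    sigma_extension_step: int = 4
    max_extensions: int = 3

    def __post_init__(self) -> None:
        if not self.n_lambda or not self.n_sigma_start:
            raise ValueError("hyperparameter grids must be non-empty")

    @staticmethod
    def lam(n_lambda: int) -> float:
        return 10.0 ** (-n_lambda)

    @staticmethod
    def sigma(n_sigma: int) -> float:
        return 10.0 ** (n_sigma / 2.0)


def pairwise_distance(X1: np.ndarray, X2: np.ndarray, kind: str) -> np.ndarray:
    """The distance the kernel consumes: L1 (laplacian) or squared L2 (gaussian)."""
    if kind == "laplacian":
        return cdist(X1, X2, metric="cityblock")
    return cdist(X1, X2, metric="sqeuclidean")


def kernel_from_distance(D: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.kind == "laplacian":
        return np.exp(-D / spec.sigma)
    return np.exp(-D / (2.0 * spec.sigma**2))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Entry-wise kernel between two feature sets (k(x, x) = 1)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature lengths differ")
    return kernel_from_distance(pairwise_distance(X1, X2, spec.kind), spec)


def krr_fit(K_train: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Dual coefficients α solving (K + λI)α = y (SPD solve, lstsq fallback)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("labels contain non-finite values")
    A = K_train + lam * np.eye(len(K_train))
    try:
        c = scipy.linalg.cho_factor(A, lower=True)
        return scipy.linalg.cho_solve(c, y)
    except scipy.linalg.LinAlgError:
        return np.linalg.lstsq(A, y, rcond=None)[0]


@dataclass
class KernelModel:
    """Fitted KRR model (stores training features and dual coefficients)."""

    spec: KernelSpec
    lam: float
    X_train: np.ndarray
    alpha: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return kernel_matrix(np.atleast_2d(X), self.X_train, self.spec) @ self.alpha


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    order = np.random.default_rng(seed).permutation(n)
    return [order[i::k] for i in range(k)]


def _cv_mae_table(
    D: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    n_sigmas: list[int],
    n_lambdas: tuple[int, ...],
    kind: str,
) -> dict[tuple[int, int], float]:
    """Mean inner-CV MAE per (n_lambda, n_sigma) cell."""
    out: dict[tuple[int, int], float] = {}
    all_idx = np.arange(len(y))
    for ns in n_sigmas:
        K_full = kernel_from_distance(D, KernelSpec(kind, KRRHyperGrid.sigma(ns)))
        maes = {nl: [] for nl in n_lambdas}
        for val in folds:
            train = np.setdiff1d(all_idx, val, assume_unique=False)
            K_tr = K_full[np.ix_(train, train)]
            K_val = K_full[np.ix_(val, train)]
            for nl in n_lambdas:
                alpha = krr_fit(K_tr, y[train], KRRHyperGrid.lam(nl))
                maes[nl].append(float(np.mean(np.abs(K_val @ alpha - y[val]))))
        for nl in n_lambdas:
            out[(nl, ns)] = float(np.mean(maes[nl]))
    return out


def select_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    grid: KRRHyperGrid | None = None,
    kernel_kind: str = "laplacian",
    inner_folds: int = 5,
    seed: int = 0,
    distance: np.ndarray | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (λ, σ) grid search by inner k-fold CV with adaptive σ range.

    If the best n_σ sits on the current grid boundary the σ grid is extended
    by ``sigma_extension_step`` in that direction, up to ``max_extensions``
    times. Ties (within 1e-6 MAE) break toward larger λ, then smaller σ.
    Returns (σ, λ, tidy CV table).
    """
    grid = grid or KRRHyperGrid()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * inner_folds:
        raise ValueError(f"need at least {2 * inner_folds} samples for {inner_folds}-fold CV")
    D = pairwise_distance(X, X, kernel_kind) if distance is None else distance
    folds = _fold_indices(n, inner_folds, seed)

    n_sigmas = sorted(grid.n_sigma_start)
    table = _cv_mae_table(D, y, folds, n_sigmas, grid.n_lambda, kernel_kind)
    for _ in range(grid.max_extensions):
        best_nl, best_ns = _pick_best(table)
        lo, hi = min(n_sigmas), max(n_sigmas)
        if best_ns == hi:
            new = list(range(hi + 1, hi + 1 + grid.sigma_extension_step))
        elif best_ns == lo and lo > _SIGMA_FLOOR:
            new = list(range(max(lo - grid.sigma_extension_step, _SIGMA_FLOOR), lo))
        else:
            break
        table.update(_cv_mae_table(D, y, folds, new, grid.n_lambda, kernel_kind))
        n_sigmas = sorted(set(n_sigmas) | set(new))
    best_nl, best_ns = _pick_best(table)
    tidy = pd.DataFrame(
        [(nl, ns, KRRHyperGrid.lam(nl), KRRHyperGrid.sigma(ns), mae)
         for (nl, ns), mae in sorted(table.items())],
        columns=["n_lambda", "n_sigma", "lam", "sigma", "cv_mae"],
    )
    return KRRHyperGrid.sigma(best_ns), KRRHyperGrid.lam(best_nl), tidy


_SIGMA_FLOOR = -12  # σ = 10^(-6): far below any useful width


def _pick_best(table: dict[tuple[int, int], float]) -> tuple[int, int]:
    best_mae = min(table.values())
    # ties toward larger λ (larger n_lambda is SMALLER λ, so prefer smaller n_lambda)
    candidates = [cell for cell, mae in table.items() if mae <= best_mae + _TIE_TOL]
    return min(candidates, key=lambda cell: (cell[0], cell[1]))


def fit_krr_model(
    X: np.ndarray,
    y: np.ndarray,
    kernel_kind: str = "laplacian",
    grid: KRRHyperGrid | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    distance: np.ndarray | None = None,
) -> KernelModel:
    """Select (σ, λ) by inner CV, then fit on the full training set."""
    sigma, lam, _ = select_hyperparameters(
        X, y, grid, kernel_kind, inner_folds=inner_folds, seed=seed, distance=distance
    )
    spec = KernelSpec(kernel_kind, sigma)
    K = kernel_matrix(X, X, spec)
    alpha = krr_fit(K, np.asarray(y, dtype=float), lam)
    return KernelModel(spec=spec, lam=lam, X_train=np.asarray(X, dtype=float), alpha=alpha)
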