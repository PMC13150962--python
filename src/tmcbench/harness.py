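"""Evaluation machinery: grouped k-fold plans, cross-model benchmarking,
charge-subset and sign/correlation error analyses, and the KRR timing
estimator."""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmcbench.chem_core import AtomicStructure, PropertyRecord, labels_frame
from tmcbench.kernel_models import (
    KRRHyperGrid,
    fit_krr_model,
    kernel_from_distance,
    pairwise_distance,
)
from tmcbench.mpnn import MPNNConfig, train_mpnn
from tmcbench.representations import FeaturizerParams, featurize_all, fit_featurizer

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "ModelSpec",
    "BenchmarkResult",
    "TimingInputs",
    "ProtocolError",
    "make_folds",
    "run_benchmark",
    "subset_mae_by_charge",
    "sign_error_rate",
    "error_correlation",
    "krr_time_estimate",
]


class ProtocolError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: dict  # structure_id -> fold index
    seed: int

    def fold_of(self, structure_id: str) -> int:
        return self.assignment[structure_id]

    def ids_in_fold(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]

    @property
    def plan_hash(self) -> str:
        payload = repr(sorted(self.assignment.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_folds(ids: list[str], groups: dict[str, str], k: int = 10, seed: int = 0) -> FoldPlan:
    """Grouped k-fold plan: groups are shuffled by seed and dealt round-robin,
    so all structures sharing a group key land in the same fold and fold sizes
    are within ±1 at the group level."""
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ProtocolError(f"ids without group key: {missing[:3]}...")
    unique_groups = sorted({groups[i] for i in ids})
    if k > len(unique_groups):
        raise ProtocolError(f"k={k} exceeds {len(unique_groups)} groups")
    order = np.random.default_rng(seed).permutation(len(unique_groups))
    fold_of_group = {unique_groups[g]: fold % k for fold, g in enumerate(order)}
    assignment = {i: fold_of_group[groups[i]] for i in ids}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def group_key(structure: AtomicStructure) -> str:
    """Default grouping: complex_id if present (keeps LS/HS and vertical
    variants of one complex in the same fold), else the structure id."""
    return structure.tags.get("complex_id", structure.id)


# ---------------------------------------------------------------------------
# model specs and benchmark results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One model entry for the benchmark.

    kind='krr': featurize with ``rep``/``variant`` and fit KRR with nested
    hyperparameter selection. kind='mpnn': train the message-passing network
    with an 8:1 train/validation carve-out inside each training fold.
    """

    name: str
    kind: str  # 'krr' | 'mpnn'
    rep: str = "slatm"
    variant: str = "global"
    kernel: str = "laplacian"
    grid: KRRHyperGrid = field(default_factory=KRRHyperGrid)
    inner_folds: int = 5
    max_train: int | None = None  # deterministic subsample cap for budget
    mpnn_config: MPNNConfig = field(default_factory=MPNNConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("krr", "mpnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class BenchmarkResult:
    fold_plan_hash: str
    seed: int
    entries: dict = field(default_factory=dict)  # (model, property) -> dict

    def mae(self, model: str, prop: str) -> float:
        return self.entries[(model, prop)]["mean_mae"]

    def table(self) -> pd.DataFrame:
        rows = [
            (m, p, e["mean_mae"], e["std_mae"], len(e["fold_maes"]))
            for (m, p), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["model", "property", "mae", "std", "n_folds"])

    def errors_frame(self, model: str, prop: str) -> pd.DataFrame:
        e = self.entries[(model, prop)]
        return pd.DataFrame(
            {
                "structure_id": e["test_ids"],
                "prediction": e["predictions"],
                "reference": e["references"],
                "error": np.asarray(e["predictions"]) - np.asarray(e["references"]),
            }
        )


def _carve_validation(
    group_sizes: dict[str, int], target: int, rng: np.random.Generator
) -> set[str]:
    """Pick whole groups whose sizes sum as close to ``target`` as possible."""
    names = list(group_sizes)
    rng.shuffle(names)
    chosen: set[str] = set()
    count = 0
    for name in names:
        if count + group_sizes[name] <= target + 1 and count < target:
            chosen.add(name)
            count += group_sizes[name]
    # repair pass: try single swaps to close any residual gap
    if abs(count - target) > 1:
        outside = [n for n in names if n not in chosen]
        for a in list(chosen):
            for b in outside:
                new = count - group_sizes[a] + group_sizes[b]
                if abs(new - target) < abs(count - target):
                    chosen.remove(a)
                    chosen.add(b)
                    count = new
                    break
            if abs(count - target) <= 1:
                break
    return chosen


def run_benchmark(
    structures: list[AtomicStructure],
    labels: list[PropertyRecord],
    model_specs: list[ModelSpec],
    plan: FoldPlan,
    properties: list[str],
    seed: int = 0,
    folds_to_run: list[int] | None = None,
    featurizer_params: FeaturizerParams | None = None,
    shared_cache: dict | None = None,
) -> BenchmarkResult:
    """Evaluate every (model, property) pair on the shared fold plan.

    Per fold: train on the remaining folds (with nested hyperparameter
    selection for KRR and a grouped 8:1 train/validation carve-out for MPNN
    models), predict the held-out fold, and accumulate absolute errors.

    ``shared_cache`` (an initially empty dict) lets repeated calls on the SAME
    structure list reuse feature matrices and distance matrices across runs
    (e.g. across fold-plan seeds).
    """
    by_id = {s.id: s for s in structures}
    wide = labels_frame(labels)
    folds = folds_to_run if folds_to_run is not None else list(range(plan.k))
    result = BenchmarkResult(fold_plan_hash=plan.plan_hash, seed=seed)

    # featurize once per (rep, variant) needed; cache distance matrices too
    ids_order = [s.id for s in structures]
    if shared_cache is None:
        shared_cache = {}
    feature_cache: dict[tuple[str, str], np.ndarray] = shared_cache.setdefault("features", {})
    distance_cache: dict[tuple[str, str, str], np.ndarray] = shared_cache.setdefault("distances", {})
    for spec in model_specs:
        if spec.kind != "krr":
            continue
        key = (spec.rep, spec.variant)
        if key not in feature_cache:
            featurizer = fit_featurizer(spec.rep, structures, featurizer_params)
            feature_cache[key] = featurize_all(featurizer, structures, spec.variant)
        dkey = (spec.rep, spec.variant, spec.kernel)
        if dkey not in distance_cache:
            X = feature_cache[key]
            distance_cache[dkey] = pairwise_distance(X, X, spec.kernel)

    row_of = {sid: i for i, sid in enumerate(ids_order)}
    for prop in properties:
        if prop not in wide.columns:
            raise ProtocolError(f"no labels for property {prop!r}")
        y_map = wide[prop].dropna().to_dict()
        for spec in model_specs:
            fold_maes, test_ids_all, preds_all, refs_all = [], [], [], []
            for fold in folds:
                test_ids = [i for i in plan.ids_in_fold(fold) if i in y_map and i in by_id]
                train_ids = [
                    i for i, f in plan.assignment.items()
                    if f != fold and i in y_map and i in by_id
                ]
                if not test_ids:
                    raise ProtocolError(f"fold {fold} has no labelled test structures for {prop}")
                preds = _fit_predict(
                    spec, train_ids, test_ids, y_map, by_id,
                    feature_cache, distance_cache, row_of, seed, fold,
                )
                refs = np.array([y_map[i] for i in test_ids])
                fold_maes.append(float(np.mean(np.abs(preds - refs))))
                test_ids_all.extend(test_ids)
                preds_all.extend(preds.tolist())
                refs_all.extend(refs.tolist())
            result.entries[(spec.name, prop)] = {
                "fold_maes": fold_maes,
                "mean_mae": float(np.mean(fold_maes)),
                "std_mae": float(np.std(fold_maes)),
                "test_ids": test_ids_all,
                "predictions": preds_all,
                "references": refs_all,
                "fold_plan_hash": plan.plan_hash,
            }
    return result


def _fit_predict(
    spec: ModelSpec,
    train_ids: list[str],
    test_ids: list[str],
    y_map: dict[str, float],
    by_id: dict[str, AtomicStructure],
    feature_cache: dict,
    distance_cache: dict,
    row_of: dict[str, int],
    seed: int,
    fold: int,
) -> np.ndarray:
    rng = np.random.default_rng((seed, fold, zlib.crc32(spec.name.encode())))
    if spec.kind == "krr":
        if spec.max_train is not None and len(train_ids) > spec.max_train:
            train_ids = list(rng.choice(train_ids, size=spec.max_train, replace=False))
        X = feature_cache[(spec.rep, spec.variant)]
        D = distance_cache[(spec.rep, spec.variant, spec.kernel)]
        tr = np.array([row_of[i] for i in train_ids])
        te = np.array([row_of[i] for i in test_ids])
        y_tr = np.array([y_map[i] for i in train_ids])
        model = fit_krr_model(
            X[tr], y_tr, spec.kernel, spec.grid,
            inner_folds=spec.inner_folds, seed=seed,
            distance=D[np.ix_(tr, tr)],
        )
        K_test = kernel_from_distance(D[np.ix_(te, tr)], model.spec)
        return K_test @ model.alpha

    # MPNN: grouped 8:1 train/validation carve-out
    train_structs = [by_id[i] for i in train_ids]
    groups: dict[str, list[str]] = {}
    for s in train_structs:
        groups.setdefault(group_key(s), []).append(s.id)
    sizes = {g: len(v) for g, v in groups.items()}
    target = round(len(train_ids) / 9.0)
    val_groups = _carve_validation(sizes, target, rng)
    val_ids = {i for g in val_groups for i in groups[g]}
    train_set = [s for s in train_structs if s.id not in val_ids]
    val_set = [s for s in train_structs if s.id in val_ids]
    if spec.max_train is not None and len(train_set) > spec.max_train:
        sel = rng.choice(len(train_set), size=spec.max_train, replace=False)
        train_set = [train_set[int(i)] for i in sel]
    cfg = spec.mpnn_config
    trained = train_mpnn(cfg, train_set, val_set, y_map)
    return trained.predict([by_id[i] for i in test_ids])


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def charge_sign(charge: int) -> str:
    return "positive" if charge > 0 else ("negative" if charge < 0 else "neutral")


def subset_mae_by_charge(
    errors: pd.DataFrame | None = None,
    charges: dict[str, int] | None = None,
    mode: str = "pooled",
    inner_k: int = 5,
    rerun: dict | None = None,
) -> pd.DataFrame:
    """Charge-sign subset MAEs.

    mode='pooled': group full-CV test errors (``errors`` frame from
    :meth:`BenchmarkResult.errors_frame`) by sign of the total charge.
    mode='within_subset': rerun an independent ``inner_k``-fold CV inside each
    subset; ``rerun`` must supply dict(structures, labels, model_spec,
    property, seed). Subsets with fewer than 2·inner_k groups are skipped
    with a logged reason.
    """
    if mode == "pooled":
        if errors is None or charges is None:
            raise ProtocolError("pooled mode needs errors frame and charges")
        df = errors.copy()
        df["subset"] = [charge_sign(charges[i]) for i in df["structure_id"]]
        rows = [
            (name, float(np.mean(np.abs(g["error"]))), len(g))
            for name, g in df.groupby("subset")
        ]
        return pd.DataFrame(rows, columns=["subset", "mae", "n"])
    if mode != "within_subset":
        raise ValueError(f"unknown mode {mode!r}")
    if rerun is None:
        raise ProtocolError("within_subset mode needs the rerun context")
    structures = rerun["structures"]
    labels = rerun["labels"]
    spec = rerun["model_spec"]
    prop = rerun["property"]
    seed = rerun.get("seed", 0)
    rows = []
    for name in ("negative", "neutral", "positive"):
        subset = [s for s in structures if charge_sign(s.total_charge) == name]
        n_groups = len({group_key(s) for s in subset})
        if n_groups < 2 * inner_k:
            logger.info("skipping %s charge subset: only %d groups (< %d)", name, n_groups, 2 * inner_k)
            continue
        sub_ids = {s.id for s in subset}
        sub_labels = [r for r in labels if r.structure_id in sub_ids]
        plan = make_folds(
            [s.id for s in subset], {s.id: group_key(s) for s in subset}, k=inner_k, seed=seed
        )
        res = run_benchmark(subset, sub_labels, [spec], plan, [prop], seed=seed)
        rows.append((name, res.mae(spec.name, prop), len(subset)))
    return pd.DataFrame(rows, columns=["subset", "mae", "n"])


def sign_error_rate(predictions: np.ndarray, references: np.ndarray) -> float:
    """Fraction of pairs whose predicted sign disagrees with the reference
    sign; exact zeros in the reference are excluded (and logged)."""
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.size == 0 or predictions.shape != references.shape:
        raise ProtocolError("need non-empty, equally sized prediction/reference arrays")
    nonzero = references != 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("sign_error_rate: excluded %d zero references", n_zero)
    if not nonzero.any():
        raise ProtocolError("all references are zero")
    return float(np.mean(np.sign(predictions[nonzero]) != np.sign(references[nonzero])))


def error_correlation(homo_errors: np.ndarray, lumo_errors: np.ndarray) -> tuple[float, float]:
    """OLS of LUMO errors on HOMO errors → (R², slope).

    Also asserts the gap-error variance identity
    Var(e_gap) = Var(e_lumo) + Var(e_homo) − 2·Cov (gap = lumo − homo).
    """
    e_h = np.asarray(homo_errors, dtype=float)
    e_l = np.asarray(lumo_errors, dtype=float)
    if e_h.size < 3 or e_h.shape != e_l.shape:
        raise ProtocolError("need at least 3 paired errors")
    e_gap = e_l - e_h
    cov = np.cov(e_h, e_l, ddof=0)
    lhs = float(np.var(e_gap))
    rhs = float(cov[1, 1] + cov[0, 0] - 2.0 * cov[0, 1])
    scale = max(1.0, abs(lhs), abs(rhs))
    assert abs(lhs - rhs) <= 1e-8 * scale, "gap-error variance identity violated"
    if np.var(e_h) == 0.0:
        return 0.0, 0.0
    slope = float(cov[0, 1] / cov[0, 0])
    r2 = 0.0 if cov[1, 1] == 0.0 else float(cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1]))
    return r2, slope


# ---------------------------------------------------------------------------
# timing estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingInputs:
    """Measured representation-generation time R and kernel-construction
    time K (seconds)."""

    R: float
    K: float

    def __post_init__(self) -> None:
        if self.R < 0 or self.K < 0:
            raise ValueError("R and K must be non-negative")


def krr_time_estimate(t: TimingInputs) -> tuple[float, float]:
    """(train, test) time estimates under 90/10 cross-validation:
    train = 0.9·R + 0.81·K, test = 0.1·R + 0.09·K."""
    return 0.9 * t.R + 0.81 * t.K, 0.1 * t.R + 0.09 * t.K
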