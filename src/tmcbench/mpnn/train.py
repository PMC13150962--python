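"""Training protocol: Adam, plateau LR decay (×0.6 after 60 stagnant epochs),
early stopping after 150 stagnant epochs, best-validation checkpointing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmcbench.chem_core import AtomicStructure
from tmcbench.mpnn.autodiff import Tensor
from tmcbench.mpnn.model import MPNN, MPNNConfig

__all__ = ["TrainedMPNN", "train_mpnn", "DivergenceError"]


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainedMPNN:
    """Training outcome; ``model`` carries the best-validation weights."""

    model: MPNN
    config: MPNNConfig
    log: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mae: float = np.inf

    def predict(self, structures: list[AtomicStructure]) -> np.ndarray:
        return self.model.predict(structures)


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train_mpnn(
    config: MPNNConfig,
    train_structures: list[AtomicStructure],
    val_structures: list[AtomicStructure],
    labels: dict[str, float],
) -> TrainedMPNN:
    """Train on L1 loss; fully deterministic under ``config.seed``.

    ``labels`` maps structure id → target value. Validation labels steer only
    the scheduler / early stop / checkpoint choice, never gradients.
    """
    if set(s.id for s in train_structures) & set(s.id for s in val_structures):
        raise ValueError("train and validation sets overlap")
    model = MPNN(config)
    graphs_feats = [model.make_graph(s) for s in train_structures]
    model.fit_scaler([f for _, f in graphs_feats])
    y_train = np.array([labels[s.id] for s in train_structures])
    if config.readout != "dipole_charges":
        model.y_mean = float(y_train.mean())
        model.y_std = float(y_train.std()) or 1.0
    y_std_train = (y_train - model.y_mean) / model.y_std

    val_gf = [model.make_graph(s) for s in val_structures]
    val_batch = model.pack([g for g, _ in val_gf], [f for _, f in val_gf])
    y_val = np.array([labels[s.id] for s in val_structures])

    opt = _Adam(model.trainable_params(), config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(train_structures)
    result = TrainedMPNN(model=model, config=config)
    best_state = model.state_dict()
    stagnant = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = model.pack(
                [graphs_feats[i][0] for i in idx], [graphs_feats[i][1] for i in idx]
            )
            opt.zero_grad()
            pred = model.forward(batch)
            loss = (pred - Tensor(y_std_train[idx])).abs().mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_pred = model.forward(val_batch).data
        if config.readout != "dipole_charges":
            val_pred = val_pred * model.y_std + model.y_mean
        val_mae = float(np.mean(np.abs(val_pred - y_val)))
        result.log.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_mae": val_mae, "lr": opt.lr}
        )
        if val_mae < result.best_val_mae - 1e-12:
            result.best_val_mae = val_mae
            result.best_epoch = epoch
            best_state = model.state_dict()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant % config.lr_patience == 0:
                opt.lr *= config.lr_factor
            if stagnant >= config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    return result
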