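"""Invariant continuous-filter message-passing network with optional
charge/spin embeddings and three readouts (global pool, metal-local,
latent-charge dipole magnitude)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tmcbench.chem_core import AtomicStructure
from tmcbench.mpnn.autodiff import Tensor, gather, scatter_sum, ssp
from tmcbench.mpnn.graph import MolGraph, build_graph, initial_node_features, radial_basis

__all__ = ["MPNNConfig", "MPNN", "PackedBatch", "EmbeddingRangeError"]

_CHARGE_RANGE = (-6, 6)
_MULTIPLICITY_RANGE = (1, 7)


class EmbeddingRangeError(ValueError):
    pass


@dataclass(frozen=True)
class MPNNConfig:
    hidden_dim: int = 64
    n_layers: int = 3
    cutoff: float = 5.0
    n_rbf: int = 32
    readout: str = "global_sum"  # global_sum | metal_local | dipole_charges
    pooling: str = "mean"  # for global_sum readout; mean handles intensive targets
    use_charge_embedding: bool = False
    use_spin_embedding: bool = False
    seed: int = 0
    learning_rate: float = 5e-3
    batch_size: int = 32
    lr_factor: float = 0.6  # reduce LR by 40% on plateau
    lr_patience: int = 60
    max_epochs: int = 512
    early_stop_patience: int = 150

    def __post_init__(self) -> None:
        if self.readout not in ("global_sum", "metal_local", "dipole_charges"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.pooling not in ("sum", "mean"):
            raise ValueError("pooling must be 'sum' or 'mean'")


@dataclass
class PackedBatch:
    """Several graphs concatenated into flat arrays for one forward pass."""

    features: np.ndarray  # (n_nodes, 6) standardized
    rbf: np.ndarray  # (n_edges, n_rbf) with cutoff envelope applied
    src: np.ndarray
    dst: np.ndarray
    graph_id: np.ndarray  # (n_nodes,)
    n_graphs: int
    node_counts: np.ndarray  # (n_graphs,)
    charge_idx: np.ndarray  # per node
    spin_idx: np.ndarray  # per node
    metal_nodes: np.ndarray  # (n_graphs,) packed node index of each metal
    rel_positions: np.ndarray  # (n_nodes, 3) node position minus graph COM
    total_charges: np.ndarray  # (n_graphs,)


class MPNN:
    """The network: parameters, graph packing, differentiable forward pass."""

    def __init__(self, config: MPNNConfig):
        self.config = config
        self.feat_mean = np.zeros(6)
        self.feat_std = np.ones(6)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters --------------------------------------------------------
    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim

        def dense(name: str, fan_in: int, fan_out: int) -> None:
            self.params[f"{name}.W"] = Tensor(
                rng.normal(size=(fan_in, fan_out)) / np.sqrt(fan_in), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)

        dense("embed", 6, h)
        for layer in range(cfg.n_layers):
            dense(f"int{layer}.filter1", cfg.n_rbf, h)
            dense(f"int{layer}.filter2", h, h)
            dense(f"int{layer}.pre", h, h)
            dense(f"int{layer}.upd1", h, h)
            dense(f"int{layer}.upd2", h, h)
        dense("read1", h, h)
        dense("read2", h, 1)
        # QS embedding tables on an independent stream so that enabling them
        # does not perturb the shared weights; baseline rows (charge 0,
        # multiplicity 1) are zero so a QS model at init matches the plain
        # model on neutral singlets.
        qs_rng = np.random.default_rng(cfg.seed + 7919)
        charge_table = 0.1 * qs_rng.normal(size=(_CHARGE_RANGE[1] - _CHARGE_RANGE[0] + 1, h))
        charge_table[-_CHARGE_RANGE[0]] = 0.0
        spin_table = 0.1 * qs_rng.normal(size=(_MULTIPLICITY_RANGE[1], h))
        spin_table[0] = 0.0
        self.params["charge_table"] = Tensor(charge_table, requires_grad=True)
        self.params["spin_table"] = Tensor(spin_table, requires_grad=True)

    def trainable_params(self) -> dict[str, Tensor]:
        out = dict(self.params)
        if not self.config.use_charge_embedding:
            out.pop("charge_table")
        if not self.config.use_spin_embedding:
            out.pop("spin_table")
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    # -- data preparation --------------------------------------------------
    def make_graph(self, structure: AtomicStructure) -> tuple[MolGraph, np.ndarray]:
        graph = build_graph(structure, cutoff=self.config.cutoff)
        return graph, initial_node_features(structure, graph)

    def fit_scaler(self, raw_features: list[np.ndarray]) -> None:
        stacked = np.vstack(raw_features)
        self.feat_mean = stacked.mean(axis=0)
        self.feat_std = np.where(stacked.std(axis=0) > 1e-12, stacked.std(axis=0), 1.0)

    def pack(self, graphs: list[MolGraph], raw_features: list[np.ndarray]) -> PackedBatch:
        cfg = self.config
        feats, rbfs, srcs, dsts, gids, charges, spins = [], [], [], [], [], [], []
        metal_nodes, rel_pos, counts, totals = [], [], [], []
        offset = 0
        for gid, (g, f) in enumerate(zip(graphs, raw_features)):
            qmin, qmax = _CHARGE_RANGE
            if not qmin <= g.total_charge <= qmax:
                raise EmbeddingRangeError(f"{g.structure_id}: charge {g.total_charge} outside {qmin}..{qmax}")
            if not _MULTIPLICITY_RANGE[0] <= g.multiplicity <= _MULTIPLICITY_RANGE[1]:
                raise EmbeddingRangeError(
                    f"{g.structure_id}: multiplicity {g.multiplicity} outside "
                    f"{_MULTIPLICITY_RANGE[0]}..{_MULTIPLICITY_RANGE[1]}"
                )
            n = g.n_nodes
            feats.append((f - self.feat_mean) / self.feat_std)
            cached = getattr(g, "_rbf_cache", None)
            if cached is None or cached.shape[1] != cfg.n_rbf:
                cached = radial_basis(g.edge_lengths, cfg.cutoff, cfg.n_rbf)
                g._rbf_cache = cached
            rbfs.append(cached)
            srcs.append(g.edges[:, 1] + offset)  # message source j
            dsts.append(g.edges[:, 0] + offset)  # aggregated at i
            gids.append(np.full(n, gid))
            charges.append(np.full(n, g.total_charge - qmin))
            spins.append(np.full(n, g.multiplicity - 1))
            metal_nodes.append((g.metal_node if g.metal_node is not None else -1) + (offset if g.metal_node is not None else 0))
            com = g.masses @ g.positions / g.masses.sum()
            rel_pos.append(g.positions - com)
            counts.append(n)
            totals.append(g.total_charge)
            offset += n
        return PackedBatch(
            features=np.vstack(feats),
            rbf=np.vstack(rbfs),
            src=np.concatenate(srcs).astype(int),
            dst=np.concatenate(dsts).astype(int),
            graph_id=np.concatenate(gids).astype(int),
            n_graphs=len(graphs),
            node_counts=np.array(counts, dtype=float),
            charge_idx=np.concatenate(charges).astype(int),
            spin_idx=np.concatenate(spins).astype(int),
            metal_nodes=np.array(metal_nodes, dtype=int),
            rel_positions=np.vstack(rel_pos),
            total_charges=np.array(totals, dtype=float),
        )

    # -- forward -----------------------------------------------------------
    def _dense(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def node_embeddings(self, batch: PackedBatch) -> Tensor:
        cfg = self.config
        h = self._dense("embed", Tensor(batch.features))
        if cfg.use_charge_embedding:
            h = h + gather(self.params["charge_table"], batch.charge_idx)
        if cfg.use_spin_embedding:
            h = h + gather(self.params["spin_table"], batch.spin_idx)
        n_nodes = batch.features.shape[0]
        rbf = Tensor(batch.rbf)
        for layer in range(cfg.n_layers):
            filt = self._dense(f"int{layer}.filter2", ssp(self._dense(f"int{layer}.filter1", rbf)))
            pre = self._dense(f"int{layer}.pre", h)
            messages = gather(pre, batch.src) * filt
            agg = scatter_sum(messages, batch.dst, n_nodes)
            h = h + self._dense(f"int{layer}.upd2", ssp(self._dense(f"int{layer}.upd1", agg)))
        return h

    def forward(self, batch: PackedBatch) -> Tensor:
        """Per-graph predictions (standardized scale for scalar readouts)."""
        cfg = self.config
        h = self.node_embeddings(batch)
        if cfg.readout == "dipole_charges":
            return self._dipole_magnitude(h, batch)
        if cfg.readout == "metal_local":
            if np.any(batch.metal_nodes < 0):
                raise ValueError("metal_local readout requires a metal node in every graph")
            pooled = gather(h, batch.metal_nodes)
        else:
            pooled = scatter_sum(h, batch.graph_id, batch.n_graphs)
            if cfg.pooling == "mean":
                pooled = pooled * (1.0 / batch.node_counts[:, None])
        out = self._dense("read2", ssp(self._dense("read1", pooled)))
        return out.sum(axis=1)  # (B,)

    def _dipole_magnitude(self, h: Tensor, batch: PackedBatch) -> Tensor:
        """Latent per-node charges, shifted to the exact total charge, then
        ‖Σ qᵢ (rᵢ − r_com)‖₂ per graph."""
        q = self._dense("read2", ssp(self._dense("read1", h)))  # (n_nodes, 1)
        total = scatter_sum(q, batch.graph_id, batch.n_graphs)  # (B, 1)
        target = batch.total_charges[:, None]
        correction = (Tensor(target) - total) * (1.0 / batch.node_counts[:, None])
        q = q + gather(correction, batch.graph_id)
        contrib = q * Tensor(batch.rel_positions)  # (n_nodes, 3)
        mu = scatter_sum(contrib, batch.graph_id, batch.n_graphs)  # (B, 3)
        return (mu * mu).sum(axis=1).sqrt()

    # -- inference ---------------------------------------------------------
    def predict(self, structures: list[AtomicStructure]) -> np.ndarray:
        graphs, feats = zip(*(self.make_graph(s) for s in structures))
        batch = self.pack(list(graphs), list(feats))
        raw = self.forward(batch).data
        if self.config.readout == "dipole_charges":
            return raw
        return raw * self.y_std + self.y_mean
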