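import numpy as np
import pytest

from conftest import random_rotation
from tmcbench.chem_core import AtomicStructure, element_record, labels_frame
from tmcbench.mpnn import (
    DegenerateGraphError,
    EmbeddingRangeError,
    MPNN,
    MPNNConfig,
    build_graph,
    initial_node_features,
    train_mpnn,
)
from tmcbench.mpnn.autodiff import Tensor, gather, scatter_sum, ssp
from tmcbench.synthetic import SyntheticDatasetSpec, generate_dataset, vertical_charge_variant

FAST = dict(hidden_dim=16, n_layers=2, n_rbf=8)


def _forward_scalar(model: MPNN, structures) -> np.ndarray:
    graphs, feats = zip(*(model.make_graph(s) for s in structures))
    return model.forward(model.pack(list(graphs), list(feats))).data


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        x = Tensor(rng.normal(size=(5, 4)))
        idx = np.array([0, 2, 2, 1, 4])
        out = scatter_sum(ssp(x @ W), idx, 5)
        loss = (gather(out, np.array([1, 2])) * Tensor(rng.normal(size=(2, 3)))).sum().abs()
        loss.backward()
        g = W.grad.copy()
        eps = 1e-6
        for i, j in [(0, 0), (2, 1), (3, 2)]:
            Wp = W.data.copy(); Wp[i, j] += eps
            Wm = W.data.copy(); Wm[i, j] -= eps

            def f(Wd):
                T = Tensor(Wd)
                out = scatter_sum(ssp(x @ T), idx, 5)
                rng2 = np.random.default_rng(0)
                rng2.normal(size=(4, 3)); rng2.normal(size=(5, 4))
                return abs(float((gather(out, np.array([1, 2])) * Tensor(rng2.normal(size=(2, 3)))).sum().data))

            num = (f(Wp) - f(Wm)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestBuildGraph:
    def test_water_single_node(self, water):
        g = build_graph(water)
        assert g.n_nodes == 1
        assert len(g.edges) == 0

    def test_octahedron_metal_degree(self, hs_iron_hexaqua):
        g = build_graph(hs_iron_hexaqua, cutoff=4.0)
        degree = np.sum(g.edges[:, 0] == g.metal_node)
        assert degree >= 6

    def test_h2_degenerate(self):
        h2 = AtomicStructure("h2", [1, 1], [[0, 0, 0], [0, 0, 0.74]], 0, 1)
        with pytest.raises(DegenerateGraphError):
            build_graph(h2)

    def test_edges_symmetric_no_self(self, hs_iron_hexaqua):
        g = build_graph(hs_iron_hexaqua)
        pairs = {(int(a), int(b)) for a, b in g.edges}
        assert all((b, a) in pairs for a, b in pairs)
        assert all(a != b for a, b in pairs)


class TestInitialNodeFeatures:
    def test_isolated_atom_closed_form(self):
        atom = AtomicStructure("fe", [26], [[0, 0, 0]], 0, 5, metal_index=0)
        g = build_graph(atom)
        f = initial_node_features(atom, g)[0]
        r = element_record(26).covalent_radius
        assert f[0] == pytest.approx(4 * np.pi * r**2, rel=1e-12)
        assert f[2] == 0.0  # occupied volume
        assert f[3] == 0.0  # neighbors
        assert f[4] == element_record(26).n_valence_electrons
        assert f[5] == element_record(26).pauling_en

    def test_rotation_invariance_exact(self, hs_iron_hexaqua):
        g = build_graph(hs_iron_hexaqua)
        ref = initial_node_features(hs_iron_hexaqua, g)
        R = random_rotation(3)
        moved = AtomicStructure(
            "m", hs_iron_hexaqua.atomic_numbers, hs_iron_hexaqua.coordinates @ R.T,
            2, 5, 0,
        )
        got = initial_node_features(moved, build_graph(moved))
        assert np.abs(np.sort(got, axis=0) - np.sort(ref, axis=0)).max() < 1e-9

    def test_equivalent_atoms_equal_features(self):
        # two O atoms at symmetric positions around a metal
        s = AtomicStructure(
            "sym", [26, 8, 8], [[0, 0, 0], [2, 0, 0], [-2, 0, 0]], 2, 5, 0
        )
        g = build_graph(s)
        feats = initial_node_features(s, g)
        o_rows = feats[s.atomic_numbers[g.node_atoms] == 8]
        assert np.abs(o_rows[0] - o_rows[1]).max() < 1e-12


class TestQSEmbedding:
    def test_disabled_identical_on_vertical_pair(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(**FAST))
        v = vertical_charge_variant(hs_iron_hexaqua)
        a = _forward_scalar(model, [hs_iron_hexaqua])
        b = _forward_scalar(model, [v])
        assert a[0] == b[0]

    def test_enabled_differs_on_vertical_pair(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(use_charge_embedding=True, use_spin_embedding=True, **FAST))
        v = vertical_charge_variant(hs_iron_hexaqua)
        assert _forward_scalar(model, [hs_iron_hexaqua])[0] != _forward_scalar(model, [v])[0]

    def test_init_identity_on_neutral_singlet(self, water):
        neutral = AtomicStructure("w", [8, 1, 1], water.coordinates, 0, 1)
        plain = MPNN(MPNNConfig(seed=5, **FAST))
        qs = MPNN(MPNNConfig(seed=5, use_charge_embedding=True, use_spin_embedding=True, **FAST))
        a = _forward_scalar(plain, [neutral])
        b = _forward_scalar(qs, [neutral])
        assert a[0] == b[0]  # bit-equal

    def test_out_of_range_charge(self, water):
        model = MPNN(MPNNConfig(use_charge_embedding=True, **FAST))
        weird = AtomicStructure("w", [8, 1, 1], water.coordinates, -8, 1)
        with pytest.raises(EmbeddingRangeError):
            _forward_scalar(model, [weird])


class TestForwardScalar:
    def test_rigid_motion_invariance(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(**FAST))
        ref = _forward_scalar(model, [hs_iron_hexaqua])[0]
        R = random_rotation(9)
        moved = AtomicStructure(
            "m", hs_iron_hexaqua.atomic_numbers,
            hs_iron_hexaqua.coordinates @ R.T + [3.0, -1.0, 0.5], 2, 5, 0,
        )
        assert _forward_scalar(model, [moved])[0] == pytest.approx(ref, abs=1e-5)

    def test_permutation_invariance_exact(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(**FAST))
        rng = np.random.default_rng(4)
        p = rng.permutation(hs_iron_hexaqua.n_atoms)
        metal = int(np.where(p == 0)[0][0])
        permuted = AtomicStructure(
            "p", hs_iron_hexaqua.atomic_numbers[p], hs_iron_hexaqua.coordinates[p], 2, 5, metal
        )
        assert _forward_scalar(model, [permuted])[0] == _forward_scalar(model, [hs_iron_hexaqua])[0]

    def test_mean_pooling_intensive(self, hs_iron_hexaqua):
        # a far-away disconnected copy leaves a mean-pooled prediction unchanged
        model = MPNN(MPNNConfig(pooling="mean", **FAST))
        doubled = AtomicStructure(
            "d",
            np.concatenate([hs_iron_hexaqua.atomic_numbers] * 2),
            np.vstack([hs_iron_hexaqua.coordinates, hs_iron_hexaqua.coordinates + 100.0]),
            4, 1, 0,
        )
        a = _forward_scalar(model, [hs_iron_hexaqua])[0]
        b = _forward_scalar(model, [doubled])[0]
        assert b == pytest.approx(a, abs=1e-9)

    def test_metal_local_readout(self, hs_iron_hexaqua, water):
        model = MPNN(MPNNConfig(readout="metal_local", **FAST))
        out = _forward_scalar(model, [hs_iron_hexaqua])
        assert np.isfinite(out).all()
        with pytest.raises(ValueError):
            _forward_scalar(model, [water])


class TestDipoleReadout:
    def test_equal_charges_centrosymmetric_zero(self):
        model = MPNN(MPNNConfig(readout="dipole_charges", **FAST))
        # zero the readout so all latent charges are equal after the shift
        model.params["read2.W"].data[:] = 0.0
        model.params["read2.b"].data[:] = 0.0
        s = AtomicStructure(
            "sym", [26, 8, 8, 8, 8, 8, 8],
            np.vstack([np.zeros(3), np.eye(3) * 2.0, -np.eye(3) * 2.0]),
            2, 5, 0,
        )
        assert _forward_scalar(model, [s])[0] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_leaves_magnitude(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(readout="dipole_charges", **FAST))
        ref = _forward_scalar(model, [hs_iron_hexaqua])[0]
        R = random_rotation(17)
        moved = AtomicStructure(
            "m", hs_iron_hexaqua.atomic_numbers, hs_iron_hexaqua.coordinates @ R.T, 2, 5, 0
        )
        assert _forward_scalar(model, [moved])[0] == pytest.approx(ref, abs=1e-4)

    def test_translation_leaves_magnitude(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(readout="dipole_charges", **FAST))
        ref = _forward_scalar(model, [hs_iron_hexaqua])[0]
        moved = AtomicStructure(
            "m", hs_iron_hexaqua.atomic_numbers, hs_iron_hexaqua.coordinates + [5.0, -3.0, 2.0],
            2, 5, 0,
        )
        assert _forward_scalar(model, [moved])[0] == pytest.approx(ref, abs=1e-9)

    def test_dipole_vector_covariant(self, hs_iron_hexaqua):
        model = MPNN(MPNNConfig(readout="dipole_charges", **FAST))
        # break the octahedral symmetry so the dipole is O(1)
        rng = np.random.default_rng(31)
        hs_iron_hexaqua = AtomicStructure(
            "dist",
            hs_iron_hexaqua.atomic_numbers,
            hs_iron_hexaqua.coordinates + 0.25 * rng.normal(size=hs_iron_hexaqua.coordinates.shape),
            2, 5, 0,
        )

        def mu_of(s):
            g, f = model.make_graph(s)
            batch = model.pack([g], [f])
            h = model.node_embeddings(batch)
            from tmcbench.mpnn.autodiff import Tensor, gather, scatter_sum, ssp

            q = model._dense("read2", ssp(model._dense("read1", h)))
            total = scatter_sum(q, batch.graph_id, 1)
            corr = (Tensor(batch.total_charges[:, None]) - total) * (1.0 / batch.node_counts[:, None])
            q = q + gather(corr, batch.graph_id)
            return scatter_sum(q * Tensor(batch.rel_positions), batch.graph_id, 1).data[0]

        mu = mu_of(hs_iron_hexaqua)
        R = random_rotation(19)
        moved = AtomicStructure(
            "m", hs_iron_hexaqua.atomic_numbers, hs_iron_hexaqua.coordinates @ R.T, 2, 5, 0
        )
        mu_rot = mu_of(moved)
        rel = np.linalg.norm(mu_rot - R @ mu) / max(np.linalg.norm(mu), 1e-12)
        assert rel < 1e-4


@pytest.fixture(scope="module")
def tiny_training_setup():
    spec = SyntheticDatasetSpec(n_complexes=50, seed=3, include_ls_hs_pairs=False)
    structures, labels, _ = generate_dataset(spec)
    # noiseless linear-in-charge target
    y = {s.id: -1.5 * s.total_charge for s in structures}
    return structures[:80], structures[80:100], y


class TestTraining:
    def test_learnability_with_qs(self, tiny_training_setup):
        train, val, y = tiny_training_setup
        cfg = MPNNConfig(
            seed=0, max_epochs=40, batch_size=32, learning_rate=8e-3,
            use_charge_embedding=True, use_spin_embedding=True, **FAST,
        )
        res = train_mpnn(cfg, train, val, y)
        sd = np.std([y[s.id] for s in train])
        assert res.best_val_mae < 0.2 * sd

    def test_seed_determinism_epoch1(self, tiny_training_setup):
        train, val, y = tiny_training_setup
        cfg = MPNNConfig(seed=1, max_epochs=1, **FAST)
        a = train_mpnn(cfg, train, val, y)
        b = train_mpnn(cfg, train, val, y)
        assert a.log[0]["train_loss"] == b.log[0]["train_loss"]

    def test_val_labels_do_not_touch_gradients(self, tiny_training_setup):
        train, val, y = tiny_training_setup
        cfg = MPNNConfig(seed=2, max_epochs=2, **FAST)
        a = train_mpnn(cfg, train, val, y)
        y_perturbed = dict(y)
        for s in val:
            y_perturbed[s.id] = y[s.id] + 100.0
        b = train_mpnn(cfg, train, val, y_perturbed)
        assert [e["train_loss"] for e in a.log] == [e["train_loss"] for e in b.log]

    def test_best_checkpoint_reported(self, tiny_training_setup):
        train, val, y = tiny_training_setup
        cfg = MPNNConfig(seed=0, max_epochs=8, **FAST)
        res = train_mpnn(cfg, train, val, y)
        assert res.best_epoch == int(np.argmin([e["val_mae"] for e in res.log]))
        pred = res.predict(val)
        mae = np.mean(np.abs(pred - [y[s.id] for s in val]))
        assert mae == pytest.approx(res.best_val_mae, rel=1e-9)

    def test_overlapping_train_val_rejected(self, tiny_training_setup):
        train, val, y = tiny_training_setup
        with pytest.raises(ValueError):
            train_mpnn(MPNNConfig(**FAST), train, train[:3], y)

    def test_lr_schedule_constants(self):
        cfg = MPNNConfig()
        assert cfg.lr_factor == 0.6
        assert cfg.lr_patience == 60
        assert cfg.max_epochs == 512
        assert cfg.early_stop_patience == 150
        assert cfg.hidden_dim == 64
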