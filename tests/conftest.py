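import numpy as np
import pytest

from tmcbench.chem_core import AtomicStructure
from tmcbench.synthetic import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def water():
    return AtomicStructure(
        "water",
        [8, 1, 1],
        [[0.0, 0.0, 0.0], [0.7572, 0.0, 0.5865], [-0.7572, 0.0, 0.5865]],
        total_charge=0,
        multiplicity=1,
    )


@pytest.fixture(scope="session")
def hs_iron_hexaqua():
    """[Fe(H2O)6]2+ HS-like octahedron built by hand (not via the generator)."""
    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    numbers, coords = [26], [np.zeros(3)]
    for u in axes:
        o = 2.15 * u
        perp = np.array([u[1], u[2], u[0]], float)
        perp -= (perp @ u) * u
        perp /= np.linalg.norm(perp)
        numbers += [8, 1, 1]
        coords += [o, o + 0.59 * u + 0.76 * perp, o + 0.59 * u - 0.76 * perp]
    return AtomicStructure(
        "fe_hexaqua", numbers, np.vstack(coords), total_charge=2, multiplicity=5, metal_index=0
    )


@pytest.fixture(scope="session")
def small_dataset():
    """25 synthetic complexes with LS/HS and vertical pairs (fast, cached)."""
    spec = SyntheticDatasetSpec(n_complexes=25, seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_structures(small_dataset):
    return small_dataset[0]


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
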