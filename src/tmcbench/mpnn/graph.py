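"""Distance-based molecular graphs (hydrogens excluded) and initial node
features from analytic overlapping-sphere geometry plus element tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tmcbench.chem_core import AtomicStructure, element_record
from tmcbench.chem_core.elements import atomic_mass

__all__ = ["MolGraph", "build_graph", "initial_node_features", "DegenerateGraphError"]

#: bonded-neighbor criterion: distance < this factor times the radius sum.
_BOND_FACTOR = 1.3


class DegenerateGraphError(ValueError):
    """No nodes remain after hydrogen exclusion."""


@dataclass
class MolGraph:
    structure_id: str
    node_atoms: np.ndarray  # indices into the structure (non-H atoms)
    edges: np.ndarray  # (n_edges, 2), symmetric, node-index pairs
    edge_lengths: np.ndarray  # Å
    positions: np.ndarray  # node coordinates, Å (kept for the dipole readout)
    masses: np.ndarray
    metal_node: int | None  # node index of the metal, if present
    total_charge: int
    multiplicity: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_atoms)


def build_graph(
    structure: AtomicStructure, cutoff: float = 5.0, exclude_hydrogens: bool = True
) -> MolGraph:
    """Nodes are non-H atoms; edges join node pairs closer than ``cutoff``."""
    z = structure.atomic_numbers
    keep = np.where(z > 1)[0] if exclude_hydrogens else np.arange(structure.n_atoms)
    if len(keep) == 0:
        raise DegenerateGraphError(f"{structure.id}: no nodes after hydrogen exclusion")
    # canonical node order (element, then coordinates) makes every downstream
    # array independent of the input atom order, so scalar outputs are
    # bitwise permutation-invariant
    c = structure.coordinates[keep]
    order = np.lexsort((c[:, 2], c[:, 1], c[:, 0], z[keep]))
    keep = keep[order]
    pos = structure.coordinates[keep]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    src, dst = np.where((dist < cutoff) & ~np.eye(len(keep), dtype=bool))
    metal_node = None
    if structure.metal_index is not None and structure.metal_index in keep:
        metal_node = int(np.where(keep == structure.metal_index)[0][0])
    return MolGraph(
        structure_id=structure.id,
        node_atoms=keep,
        edges=np.stack([src, dst], axis=1) if len(src) else np.zeros((0, 2), dtype=int),
        edge_lengths=dist[src, dst],
        positions=pos,
        masses=np.array([atomic_mass(int(z[i])) for i in keep]),
        metal_node=metal_node,
        total_charge=structure.total_charge,
        multiplicity=structure.multiplicity,
    )


def _cap_height(r_a: float, r_b: float, d: float) -> float:
    """Height of the spherical cap cut from sphere a by overlapping sphere b."""
    if d >= r_a + r_b:
        return 0.0
    if d <= abs(r_a - r_b):
        return 2.0 * r_a if r_b >= r_a else 0.0
    return (r_b - r_a + d) * (r_b + r_a - d) / (2.0 * d)


def initial_node_features(structure: AtomicStructure, graph: MolGraph) -> np.ndarray:
    """Raw (unstandardized) 6-vector per node.

    Order: exposed sphere surface, exposed sphere volume, occupied volume
    (sum of overlap-cap volumes), bonded-neighbor count, valence electron
    count, Pauling electronegativity. Sphere overlaps use analytic
    sphere-sphere cap formulas on covalent-radius spheres over ALL atoms
    (hydrogens shape the geometry features even though they are not nodes).
    """
    coords = structure.coordinates
    z = structure.atomic_numbers
    radii = np.array([element_record(int(zi)).covalent_radius for zi in z])
    features = np.zeros((graph.n_nodes, 6))
    for row, i in enumerate(graph.node_atoms):
        r_i = radii[i]
        surface = 4.0 * np.pi * r_i**2
        volume = 4.0 / 3.0 * np.pi * r_i**3
        occupied = 0.0
        n_bonded = 0
        for j in range(structure.n_atoms):
            if j == i:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            r_j = radii[j]
            if d < _BOND_FACTOR * (r_i + r_j):
                n_bonded += 1
            h_i = _cap_height(r_i, r_j, d)
            h_j = _cap_height(r_j, r_i, d)
            if h_i > 0.0:
                surface -= 2.0 * np.pi * r_i * h_i
                cap_i = np.pi * h_i**2 * (3.0 * r_i - h_i) / 3.0
                cap_j = np.pi * h_j**2 * (3.0 * r_j - h_j) / 3.0
                volume -= cap_i
                occupied += cap_i + cap_j
        record = element_record(int(z[i]))
        features[row] = [
            max(surface, 0.0),
            max(volume, 0.0),
            occupied,
            float(n_bonded),
            float(record.n_valence_electrons),
            record.pauling_en,
        ]
    return features


def radial_basis(distances: np.ndarray, cutoff: float, n_rbf: int) -> np.ndarray:
    """Gaussian distance expansion with a smooth cosine cutoff envelope."""
    centers = np.linspace(0.0, cutoff, n_rbf)
    width = cutoff / (n_rbf - 1)
    rbf = np.exp(-0.5 * ((distances[:, None] - centers[None, :]) / width) ** 2)
    envelope = 0.5 * (np.cos(np.pi * np.clip(distances / cutoff, 0.0, 1.0)) + 1.0)
    return rbf * envelope[:, None]
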