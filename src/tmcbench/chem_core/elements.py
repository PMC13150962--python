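"""Element tables: symbols, electronegativities, radii, valence counts,
and one-electron-Hamiltonian shell parameters loaded from packaged CSV."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "ElementRecord",
    "D_BLOCK",
    "atomic_number",
    "element_record",
    "group_number",
    "symbol_of",
]

_SYMBOLS = (
    "X H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca "
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr "
    "Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe Cs Ba La Ce Pr Nd "
    "Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg "
    "Tl Pb Bi Po At Rn"
).split()

_SYMBOL_TO_Z = {s: z for z, s in enumerate(_SYMBOLS) if z > 0}

# Pauling electronegativities; noble gases without a standard value get 0.0.
_PAULING_EN = {
    1: 2.20, 2: 0.0, 3: 0.98, 4: 1.57, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44,
    9: 3.98, 10: 0.0, 11: 0.93, 12: 1.31, 13: 1.61, 14: 1.90, 15: 2.19,
    16: 2.58, 17: 3.16, 18: 0.0, 19: 0.82, 20: 1.00, 21: 1.36, 22: 1.54,
    23: 1.63, 24: 1.66, 25: 1.55, 26: 1.83, 27: 1.88, 28: 1.91, 29: 1.90,
    30: 1.65, 31: 1.81, 32: 2.01, 33: 2.18, 34: 2.55, 35: 2.96, 36: 3.00,
    37: 0.82, 38: 0.95, 39: 1.22, 40: 1.33, 41: 1.60, 42: 2.16, 43: 1.90,
    44: 2.20, 45: 2.28, 46: 2.20, 47: 1.93, 48: 1.69, 49: 1.78, 50: 1.96,
    51: 2.05, 52: 2.10, 53: 2.66, 54: 2.60, 55: 0.79, 56: 0.89,
    72: 1.30, 73: 1.50, 74: 2.36, 75: 1.90, 76: 2.20, 77: 2.20, 78: 2.28,
    79: 2.54, 80: 2.00, 81: 1.62, 82: 2.33, 83: 2.02, 84: 2.00, 85: 2.20,
    86: 0.0,
}

# Single-bond covalent radii (Å), Cordero-style consensus values.
_COVALENT_RADIUS = {
    1: 0.31, 2: 0.28, 3: 1.28, 4: 0.96, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66,
    9: 0.57, 10: 0.58, 11: 1.66, 12: 1.41, 13: 1.21, 14: 1.11, 15: 1.07,
    16: 1.05, 17: 1.02, 18: 1.06, 19: 2.03, 20: 1.76, 21: 1.70, 22: 1.60,
    23: 1.53, 24: 1.39, 25: 1.50, 26: 1.42, 27: 1.38, 28: 1.24, 29: 1.32,
    30: 1.22, 31: 1.22, 32: 1.20, 33: 1.19, 34: 1.20, 35: 1.20, 36: 1.16,
    37: 2.20, 38: 1.95, 39: 1.90, 40: 1.75, 41: 1.64, 42: 1.54, 43: 1.47,
    44: 1.46, 45: 1.42, 46: 1.39, 47: 1.45, 48: 1.44, 49: 1.42, 50: 1.39,
    51: 1.39, 52: 1.38, 53: 1.39, 54: 1.40, 55: 2.44, 56: 2.15, 72: 1.75,
    73: 1.70, 74: 1.62, 75: 1.51, 76: 1.44, 77: 1.41, 78: 1.36, 79: 1.36,
    80: 1.32, 81: 1.45, 82: 1.46, 83: 1.48, 84: 1.40, 85: 1.50, 86: 1.50,
}

# Standard atomic weights for the light elements; heavier elements fall back
# to a linear estimate (adequate for center-of-mass weighting only).
_ATOMIC_MASS = {
    1: 1.008, 2: 4.003, 3: 6.94, 4: 9.012, 5: 10.81, 6: 12.011, 7: 14.007,
    8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305, 13: 26.982,
    14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948, 19: 39.098,
    20: 40.078, 21: 44.956, 22: 47.867, 23: 50.942, 24: 51.996, 25: 54.938,
    26: 55.845, 27: 58.933, 28: 58.693, 29: 63.546, 30: 65.38, 31: 69.723,
    32: 72.630, 33: 74.922, 34: 78.971, 35: 79.904, 36: 83.798,
}


def atomic_mass(z: int) -> float:
    """Standard atomic weight (amu); linear fallback for Z > 36."""
    return _ATOMIC_MASS.get(z, 2.2 * z)


#: d-block atomic numbers used for metal detection (3d, 4d, 5d rows).
D_BLOCK = frozenset(range(21, 31)) | frozenset(range(39, 49)) | frozenset(range(72, 81))

_LANTHANIDES = frozenset(range(57, 72))


def symbol_of(z: int) -> str:
    """Element symbol for atomic number ``z``."""
    if not 1 <= z < len(_SYMBOLS):
        raise ValueError(f"unsupported atomic number {z}")
    return _SYMBOLS[z]


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol (case-sensitive)."""
    try:
        return _SYMBOL_TO_Z[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


def group_number(z: int) -> int:
    """Periodic-table group (1–18) of element ``z``."""
    if z in (1, 2):
        return 1 if z == 1 else 18
    for start, width in ((3, 8), (11, 8), (19, 18), (37, 18)):
        if start <= z < start + width:
            offset = z - start + 1
            return offset if width == 18 or offset <= 2 else offset + 10
    if 55 <= z <= 86:
        if z in _LANTHANIDES:
            raise ValueError(f"lanthanide Z={z} carries no group assignment here")
        offset = z - 54
        return offset if offset <= 2 else offset - 14
    raise ValueError(f"unsupported atomic number {z}")


def n_valence_electrons(z: int) -> int:
    """Tabulated valence-electron count (group-based convention)."""
    g = group_number(z)
    return g if g <= 12 else g - 10


@dataclass(frozen=True)
class ElementRecord:
    """Per-element scalar data plus valence-shell parameters.

    ``eh_shells`` lists ``(shell_label, ionization_energy_eV, slater_exponent)``
    for the shells entering the minimal valence basis; ionization energies are
    negative (orbital-energy convention).
    """

    Z: int
    symbol: str
    pauling_en: float
    n_valence_electrons: int
    covalent_radius: float
    eh_shells: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.covalent_radius <= 0:
            raise ValueError(f"non-positive radius for Z={self.Z}")
        for label, energy, zeta in self.eh_shells:
            if energy >= 0:
                raise ValueError(f"shell {label} of Z={self.Z}: energy must be < 0 eV")
            if zeta <= 0:
                raise ValueError(f"shell {label} of Z={self.Z}: exponent must be > 0")


@lru_cache(maxsize=1)
def _eh_table() -> dict[int, list[tuple[str, float, float]]]:
    table: dict[int, list[tuple[str, float, float]]] = {}
    path = resources.files("tmcbench.data").joinpath("eh_params.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            z = int(row["Z"])
            table.setdefault(z, []).append(
                (row["shell"], float(row["ionization_energy_ev"]), float(row["slater_exponent"]))
            )
    return table


@lru_cache(maxsize=None)
def element_record(z: int) -> ElementRecord:
    """Full :class:`ElementRecord` for atomic number ``z``.

    Raises ``ValueError`` for elements without tabulated parameters
    (lanthanides and Z > 80 beyond the supported range).
    """
    if z not in _PAULING_EN or z not in _COVALENT_RADIUS:
        raise ValueError(f"no element data for Z={z}")
    shells = _eh_table().get(z)
    if not shells:
        raise ValueError(f"no valence-shell parameters for Z={z} ({symbol_of(z)})")
    return ElementRecord(
        Z=z,
        symbol=symbol_of(z),
        pauling_en=_PAULING_EN[z],
        n_valence_electrons=n_valence_electrons(z),
        covalent_radius=_COVALENT_RADIUS[z],
        eh_shells=list(shells),
    )
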