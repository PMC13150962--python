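"""Shared featurizer machinery: fitted layouts, parameter hashing, caching."""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field

import numpy as np

from tmcbench.chem_core import AtomicStructure
from tmcbench.guess_electronic import GuessElectronicState, solve_state

__all__ = [
    "FeaturizerParams",
    "LayoutError",
    "RepresentationVector",
    "UnsupportedVariantError",
    "Featurizer",
    "featurize_all",
    "get_state",
]


class LayoutError(ValueError):
    """Structure incompatible with the fitted feature layout."""


class UnsupportedVariantError(ValueError):
    """Requested global/local variant is not defined for this representation."""


@dataclass(frozen=True)
class FeaturizerParams:
    """Hyperparameters for all four representations (this artifact's defaults)."""

    # bagged many-body spectra
    slatm_r_min: float = 0.8
    slatm_r_cut: float = 4.8
    slatm_r_step: float = 0.1
    slatm_width: float = 0.05
    slatm_angle_step: float = np.pi / 20
    slatm_angle_width: float = 0.1
    # smooth-density power spectrum
    soap_r_cut: float = 4.5
    soap_sigma: float = 0.4
    soap_n_max: int = 4
    soap_l_max: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.slatm_r_min < self.slatm_r_cut:
            raise ValueError("need 0 < r_min < r_cut")
        if self.soap_r_cut <= 0 or self.soap_sigma <= 0:
            raise ValueError("SOAP cutoff and width must be positive")


@dataclass
class RepresentationVector:
    values: np.ndarray
    layout: list[tuple[str, int, int]]  # (bag/channel name, offset, length)
    rep_name: str
    variant: str
    params_hash: str

    def __post_init__(self) -> None:
        total = sum(length for _, _, length in self.layout)
        if total != len(self.values):
            raise ValueError("layout lengths do not sum to vector length")

    def bag(self, name: str) -> np.ndarray:
        for bag_name, offset, length in self.layout:
            if bag_name == name:
                return self.values[offset : offset + length]
        raise KeyError(name)


class Featurizer:
    """Base class: freezes the element set at fit time and hashes parameters."""

    rep_name: str = "base"

    def __init__(self, structures: list[AtomicStructure], params: FeaturizerParams):
        if not structures:
            raise ValueError("cannot fit a featurizer on an empty structure list")
        self.params = params
        self.elements: tuple[int, ...] = tuple(
            sorted({int(z) for s in structures for z in s.atomic_numbers})
        )
        self._finalize_fit(structures)
        self.layout: list[tuple[str, int, int]] = self._build_layout()
        self.params_hash = self._hash()

    # hooks ----------------------------------------------------------------
    def _finalize_fit(self, structures: list[AtomicStructure]) -> None:  # noqa: B027
        pass

    def _build_layout(self) -> list[tuple[str, int, int]]:
        raise NotImplementedError

    def _transform(self, structure: AtomicStructure, variant: str) -> np.ndarray:
        raise NotImplementedError

    # api ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return sum(length for _, _, length in self.layout)

    def _hash(self) -> str:
        payload = repr((self.rep_name, self.params, self.elements, self._extra_state()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def _extra_state(self) -> tuple:
        return ()

    def _check_elements(self, structure: AtomicStructure) -> None:
        unseen = {int(z) for z in structure.atomic_numbers} - set(self.elements)
        if unseen:
            raise LayoutError(
                f"{structure.id}: element(s) Z={sorted(unseen)} not seen at fit time"
            )

    def transform(self, structure: AtomicStructure, variant: str = "global") -> RepresentationVector:
        if variant not in ("global", "local"):
            raise UnsupportedVariantError(f"unknown variant {variant!r}")
        if variant == "local" and structure.metal_index is None:
            raise UnsupportedVariantError(
                f"{structure.id}: local variant requires metal_index"
            )
        self._check_elements(structure)
        values = self._transform(structure, variant)
        return RepresentationVector(
            values=values,
            layout=self.layout,
            rep_name=self.rep_name,
            variant=variant,
            params_hash=self.params_hash,
        )


def featurize_all(
    featurizer: Featurizer, structures: list[AtomicStructure], variant: str = "global"
) -> np.ndarray:
    """Stack representation vectors row-wise into a design matrix."""
    return np.vstack([featurizer.transform(s, variant).values for s in structures])


# -- one-electron state cache ---------------------------------------------

_STATE_CACHE: dict[tuple, GuessElectronicState] = {}
_STATE_CACHE_MAX = 4096


def _structure_key(structure: AtomicStructure) -> tuple:
    return (
        structure.id,
        structure.total_charge,
        structure.multiplicity,
        zlib.crc32(structure.atomic_numbers.tobytes()),
        zlib.crc32(np.ascontiguousarray(structure.coordinates).tobytes()),
    )


def get_state(structure: AtomicStructure) -> GuessElectronicState:
    """Memoized one-electron solve (shared by the electronic featurizers)."""
    key = _structure_key(structure)
    state = _STATE_CACHE.get(key)
    if state is None:
        state = solve_state(structure)
        if len(_STATE_CACHE) >= _STATE_CACHE_MAX:
            _STATE_CACHE.pop(next(iter(_STATE_CACHE)))
        _STATE_CACHE[key] = state
    return state
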