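"""Extended-XYZ (multi-frame) and label-CSV input/output.

Dialect: the comment line holds space-separated ``key=value`` pairs; ``charge``
and ``multiplicity`` are required on read, ``id`` and arbitrary string tags are
preserved. Coordinates are written in Å with 8 decimal places.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from tmcbench.chem_core.elements import atomic_number, symbol_of
from tmcbench.chem_core.model import (
    PROPERTY_UNITS,
    AtomicStructure,
    PropertyRecord,
    ValidationError,
)

__all__ = ["read_extxyz", "write_extxyz", "read_labels", "write_labels"]

_RESERVED_KEYS = ("id", "charge", "multiplicity", "metal_index")


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ frame, reporting the frame index."""


def _parse_comment(line: str) -> dict[str, str]:
    pairs = {}
    for token in line.split():
        if "=" not in token:
            raise ValueError(f"comment token {token!r} is not key=value")
        key, value = token.split("=", 1)
        pairs[key] = value
    return pairs


def read_extxyz(path: str | os.PathLike) -> list[AtomicStructure]:
    """Read all frames of an extended-XYZ file into validated structures."""
    structures: list[AtomicStructure] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pos, frame = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
            if natoms < 1 or pos + 1 + natoms >= len(lines) + 1:
                raise ValueError
            meta = _parse_comment(lines[pos + 1])
            numbers, coords = [], []
            for ln in lines[pos + 2 : pos + 2 + natoms]:
                parts = ln.split()
                numbers.append(atomic_number(parts[0]))
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            if len(numbers) != natoms:
                raise ValueError
            charge = int(meta["charge"])
            multiplicity = int(meta["multiplicity"])
        except (ValueError, KeyError, IndexError) as exc:
            raise ExtXYZParseError(f"malformed frame {frame} in {path}: {exc}") from exc
        metal_index = int(meta["metal_index"]) if "metal_index" in meta else None
        tags = {k: v for k, v in meta.items() if k not in _RESERVED_KEYS}
        structure = AtomicStructure(
            id=meta.get("id", f"frame{frame}"),
            atomic_numbers=np.array(numbers),
            coordinates=np.array(coords),
            total_charge=charge,
            multiplicity=multiplicity,
            metal_index=metal_index,
            tags=tags,
        ).with_metal_inferred()
        structures.append(structure)
        pos += 2 + natoms
        frame += 1
    return structures


def write_extxyz(path: str | os.PathLike, structures: Iterable[AtomicStructure]) -> None:
    """Write structures as a multi-frame extended-XYZ file (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            fields = [f"id={s.id}", f"charge={s.total_charge}", f"multiplicity={s.multiplicity}"]
            if s.metal_index is not None:
                fields.append(f"metal_index={s.metal_index}")
            fields.extend(f"{k}={v}" for k, v in sorted(s.tags.items()))
            fh.write(" ".join(fields) + "\n")
            for z, xyz in zip(s.atomic_numbers, s.coordinates):
                fh.write(
                    f"{symbol_of(int(z)):<2s} "
                    f"{xyz[0]:16.8f} {xyz[1]:16.8f} {xyz[2]:16.8f}\n"
                )


def read_labels(path: str | os.PathLike) -> list[PropertyRecord]:
    """Read a label table (CSV: structure_id,property_name,value,units)."""
    df = pd.read_csv(path, dtype={"structure_id": str})
    missing = {"structure_id", "property_name", "value", "units"} - set(df.columns)
    if missing:
        raise ValidationError(f"label table missing columns {sorted(missing)}")
    records = [
        PropertyRecord(row.structure_id, row.property_name, float(row.value), row.units)
        for row in df.itertuples()
    ]
    _check_gap_consistency(records)
    return records


def write_labels(path: str | os.PathLike, records: Iterable[PropertyRecord]) -> None:
    df = pd.DataFrame(
        [(r.structure_id, r.property_name, r.value, r.units) for r in records],
        columns=["structure_id", "property_name", "value", "units"],
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _check_gap_consistency(records: list[PropertyRecord], tol: float = 1e-6) -> None:
    by_id: dict[str, dict[str, float]] = {}
    for r in records:
        by_id.setdefault(r.structure_id, {})[r.property_name] = r.value
    for sid, props in by_id.items():
        if {"homo", "lumo", "gap"} <= props.keys():
            if abs(props["gap"] - (props["lumo"] - props["homo"])) > tol:
                raise ValidationError(f"{sid}: gap != lumo - homo")


def labels_frame(records: Iterable[PropertyRecord]) -> pd.DataFrame:
    """Wide table: one row per structure_id, one column per property."""
    df = pd.DataFrame(
        [(r.structure_id, r.property_name, r.value) for r in records],
        columns=["structure_id", "property_name", "value"],
    )
    return df.pivot(index="structure_id", columns="property_name", values="value")
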