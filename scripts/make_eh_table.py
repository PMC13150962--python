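"""Regenerate src/tmcbench/data/eh_params.csv.

Valence-shell parameters (valence-state ionization energies in eV, single-zeta
Slater exponents) for H–Hg excluding lanthanides. Literature extended-Hueckel
values are used where well established; remaining elements fall back to
Slater's screening rules for exponents and electronegativity-scaled estimates
for ionization energies. The table is a pragmatic, versioned parameterization
for a one-shot guess Hamiltonian, not a claim of spectroscopic accuracy.

Run from the repository root:  python scripts/make_eh_table.py
"""

from __future__ import annotations

import csv
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from tmcbench.chem_core.elements import (  # noqa: E402
    _LANTHANIDES,
    _PAULING_EN,
    group_number,
    symbol_of,
)

# (Z, shell) -> (VSIE eV, zeta); classic Hoffmann/Alvarez-style parameters.
OVERRIDES: dict[tuple[int, str], tuple[float, float]] = {
    (1, "1s"): (-13.6, 1.30),
    (3, "2s"): (-5.4, 0.65), (3, "2p"): (-3.5, 0.65),
    (4, "2s"): (-10.0, 0.975), (4, "2p"): (-6.0, 0.975),
    (5, "2s"): (-15.2, 1.30), (5, "2p"): (-8.5, 1.30),
    (6, "2s"): (-21.4, 1.625), (6, "2p"): (-11.4, 1.625),
    (7, "2s"): (-26.0, 1.95), (7, "2p"): (-13.4, 1.95),
    (8, "2s"): (-32.3, 2.275), (8, "2p"): (-14.8, 2.275),
    (9, "2s"): (-40.0, 2.425), (9, "2p"): (-18.1, 2.425),
    (11, "3s"): (-5.1, 0.733), (11, "3p"): (-3.0, 0.733),
    (12, "3s"): (-9.0, 1.10), (12, "3p"): (-4.5, 1.10),
    (13, "3s"): (-12.3, 1.167), (13, "3p"): (-6.5, 1.167),
    (14, "3s"): (-17.3, 1.383), (14, "3p"): (-9.2, 1.383),
    (15, "3s"): (-18.6, 1.60), (15, "3p"): (-14.0, 1.60),
    (16, "3s"): (-20.0, 1.817), (16, "3p"): (-13.3, 1.817),
    (17, "3s"): (-30.0, 2.033), (17, "3p"): (-15.0, 2.033),
    (19, "4s"): (-4.34, 0.874), (19, "4p"): (-2.73, 0.874),
    (20, "4s"): (-7.0, 1.20), (20, "4p"): (-4.0, 1.20),
    # 3d series: 4s / 4p / 3d
    (21, "4s"): (-8.87, 1.30), (21, "4p"): (-2.75, 1.30), (21, "3d"): (-8.51, 2.40),
    (22, "4s"): (-8.97, 1.40), (22, "4p"): (-5.44, 1.40), (22, "3d"): (-10.81, 2.55),
    (23, "4s"): (-8.81, 1.45), (23, "4p"): (-5.52, 1.45), (23, "3d"): (-11.00, 2.70),
    (24, "4s"): (-8.66, 1.55), (24, "4p"): (-5.24, 1.55), (24, "3d"): (-11.22, 2.85),
    (25, "4s"): (-9.75, 1.60), (25, "4p"): (-5.89, 1.60), (25, "3d"): (-11.67, 3.00),
    (26, "4s"): (-9.10, 1.70), (26, "4p"): (-5.32, 1.70), (26, "3d"): (-12.60, 3.15),
    (27, "4s"): (-9.21, 1.75), (27, "4p"): (-5.29, 1.75), (27, "3d"): (-13.18, 3.30),
    (28, "4s"): (-9.17, 1.80), (28, "4p"): (-5.15, 1.80), (28, "3d"): (-13.49, 3.45),
    (29, "4s"): (-11.40, 1.85), (29, "4p"): (-6.06, 1.85), (29, "3d"): (-14.00, 3.60),
    (30, "4s"): (-12.41, 1.90), (30, "4p"): (-6.53, 1.90), (30, "3d"): (-15.00, 3.75),
    (35, "4s"): (-27.0, 2.054), (35, "4p"): (-13.1, 2.054),
    (53, "5s"): (-23.0, 1.90), (53, "5p"): (-12.7, 1.90),
}

N_STAR = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7, 5: 4.0, 6: 4.2}


def _config(z: int) -> list[tuple[int, str, int]]:
    """Aufbau (n, l, count) occupation used only for Slater screening."""
    order = [
        (1, "s", 2), (2, "s", 2), (2, "p", 6), (3, "s", 2), (3, "p", 6),
        (4, "s", 2), (3, "d", 10), (4, "p", 6), (5, "s", 2), (4, "d", 10),
        (5, "p", 6), (6, "s", 2), (4, "f", 14), (5, "d", 10), (6, "p", 6),
    ]
    out, remaining = [], z
    for n, l, cap in order:
        if remaining <= 0:
            break
        take = min(cap, remaining)
        out.append((n, l, take))
        remaining -= take
    return out


def slater_zeta(z: int, n: int, l: str) -> float:
    cfg = _config(z)
    shield = 0.0
    for cn, cl, cnt in cfg:
        if cl in ("s", "p") and l in ("s", "p"):
            same_group = cn == n
        else:
            same_group = (cn, cl) == (n, l)
        if same_group:
            shield += 0.35 * max(cnt - 1, 0) if (n, l) != (1, "s") else 0.30 * max(cnt - 1, 0)
        elif l in ("s", "p") and cn == n - 1:
            shield += 0.85 * cnt
        elif cn < n or (l == "d" and (cn < n or (cn == n and cl in ("s", "p")))):
            shield += 1.00 * cnt
    return max((z - shield) / N_STAR[n], 0.5)


def fallback_vsie(z: int, l: str) -> float:
    en = max(_PAULING_EN.get(z, 1.5), 0.7)
    g = group_number(z)
    if l == "d":
        return -(8.0 + 0.55 * (g - 3))
    if l == "p":
        if 3 <= g <= 12:  # d-block np: high-lying
            return -5.5
        return -max(4.4 * en, 3.0)
    return -max(8.3 * en, 4.3)


def valence_shells(z: int) -> list[tuple[int, str]]:
    if z <= 2:
        return [(1, "s")]
    period = next(p for p, hi in ((2, 10), (3, 18), (4, 36), (5, 54), (6, 86)) if z <= hi)
    g = group_number(z)
    shells: list[tuple[int, str]] = []
    if period >= 4 and 3 <= g <= 12:
        shells.append((period - 1, "d"))
    shells.extend([(period, "s"), (period, "p")])
    return shells


def main() -> None:
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "tmcbench" / "data" / "eh_params.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for z in range(1, 81):
        if z in _LANTHANIDES:
            continue
        for n, l in valence_shells(z):
            shell = f"{n}{l}"
            if (z, shell) in OVERRIDES:
                vsie, zeta = OVERRIDES[(z, shell)]
            else:
                vsie, zeta = fallback_vsie(z, l), slater_zeta(z, n, l)
            rows.append((z, symbol_of(z), shell, round(vsie, 3), round(zeta, 4)))
    with out.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Z", "symbol", "shell", "ionization_energy_ev", "slater_exponent"])
        w.writerows(rows)
    print(f"wrote {len(rows)} rows to {out}")


if __name__ == "__main__":
    main()
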