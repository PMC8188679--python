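"""Elemental and residue mass bookkeeping.

All masses in the package derive from the monoisotopic element masses in
:data:`ELEMENT_MASS`; no ion m/z value is hard-coded anywhere in the
library. Glycan residue masses are *residue* (in-chain, water-free)
masses; amino-acid masses likewise.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

# Monoisotopic element masses (Da).
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Na": 22.98976928,
}

#: Mass of a proton (charge carrier), Da.
PROTON = 1.00727646688
#: Mass of an electron, Da.
ELECTRON = 0.00054857990946

WATER = {"H": 2, "O": 1}
AMMONIA = {"N": 1, "H": 3}
METHYLENE = {"C": 1, "H": 2}  # net addition of one methyl for one H


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental formula given as element->count."""
    try:
        return sum(ELEMENT_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


def combine(*formulas: Mapping[str, int]) -> dict[str, int]:
    """Sum elemental formulas (element-wise)."""
    total: Counter[str] = Counter()
    for f in formulas:
        total.update(f)
    return dict(total)


# Glycan residue (water-free) elemental formulas.
GLYCAN_RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
}

# Free OH/NH positions per in-chain residue that receive a methyl group on
# permethylation (one glycosidic linkage assumed consumed per residue; the
# non-reducing terminus contributes one extra site, accounted for at the
# glycan level).
PERMETHYLATION_SITES: dict[str, int] = {
    "Hex": 3,
    "HexNAc": 3,   # 2 OH + acetamido NH
    "dHex": 2,
    "NeuAc": 5,    # 4 OH + carboxyl O-methyl ester
}

# Amino-acid residue monoisotopic masses (water-free), standard 20 letters.
_AA_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

AA_RESIDUE_MASS: dict[str, float] = {
    aa: formula_mass(f) for aa, f in _AA_FORMULA.items()
}

WATER_MASS = formula_mass(WATER)
AMMONIA_MASS = formula_mass(AMMONIA)
METHYLENE_MASS = formula_mass(METHYLENE)
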