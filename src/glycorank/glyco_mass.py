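"""Mass calculus and annotation for permethylated benzyl O-glycans.

Cellular O-glycome reporter/amplification (CORA) feeds cells a benzyl-GalNAc
mimetic; the secreted benzyl glycosides are permethylated and profiled by
nanoLC-ESI-MS. This module computes the singly charged monoisotopic m/z of
any Hex/HexNAc/dHex/NeuAc composition from elemental formulas, computes
native oxonium (oxocarbenium) fragment masses used as glycopeptide
diagnostics, and annotates/quantifies O-glycome peak lists against a glycan
library.

The neutral permethylated benzyl glycoside decomposes as::

    M = sum(residue increments) + H2O + (benzyl - H) + CH2

where each residue increment is the water-free residue mass plus one methyl
per free OH/NH of an in-chain residue, and the trailing CH2 is the extra
methyl on the single non-reducing terminus that every tree topology of a
given composition shares (each extra branch terminus is offset by the lost
hydroxyl at its branch point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    ELECTRON,
    ELEMENT_MASS,
    GLYCAN_RESIDUE_FORMULA,
    METHYLENE_MASS,
    PERMETHYLATION_SITES,
    PROTON,
    WATER_MASS,
    formula_mass,
)

__all__ = [
    "MonosaccharideComposition",
    "GlycanReferenceEntry",
    "PeakList",
    "GlycanAssignment",
    "OGlycomeProfile",
    "permethylated_residue_increment",
    "permethylated_bn_mz",
    "oxonium_mz",
    "annotate_oglycome",
    "default_library",
]

# benzyl aglycone replaces the anomeric hydroxyl hydrogen: net +C7H6
_BENZYL_MINUS_H = formula_mass({"C": 7, "H": 6})

_RESIDUE_KINDS = ("Hex", "HexNAc", "dHex", "NeuAc")


class UnsupportedResidueError(ValueError):
    """Raised for a monosaccharide kind outside Hex/HexNAc/dHex/NeuAc."""


class InvalidCompositionError(ValueError):
    """Raised for empty compositions or compositions without the GalNAc core."""


@dataclass(frozen=True, order=True)
class MonosaccharideComposition:
    """Counts of the four monosaccharide classes defining a glycan species."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InvalidCompositionError(
                    f"{name} count must be a non-negative integer, got {v!r}"
                )

    @property
    def total(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac

    def counts(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "dHex": self.dhex,
            "NeuAc": self.neuac,
        }

    def __str__(self) -> str:
        parts = [f"{k}{n}" for k, n in self.counts().items() if n]
        return "".join(parts) or "empty"


def permethylated_residue_increment(kind: str) -> float:
    """Mass added when one permethylated residue extends a permethylated glycan.

    Linkage-independent: the new glycosidic bond consumes one methylation
    site on the incoming residue and creates one on neither partner, so the
    increment is the water-free residue mass plus the in-chain methyl count.
    """
    if kind not in _RESIDUE_KINDS:
        raise UnsupportedResidueError(f"unsupported residue kind {kind!r}")
    return (
        formula_mass(GLYCAN_RESIDUE_FORMULA[kind])
        + PERMETHYLATION_SITES[kind] * METHYLENE_MASS
    )


def permethylated_bn_mz(
    composition: MonosaccharideComposition, adduct: str = "proton"
) -> float:
    """Singly charged monoisotopic m/z of the permethylated benzyl glycoside.

    The default proton adduct reproduces the printed CORA ion ladder;
    ``adduct="sodium"`` gives the [M+Na]+ species common for permethylated
    glycans.
    """
    if composition.total == 0:
        raise InvalidCompositionError("empty composition has no mass")
    if composition.hexnac < 1:
        raise InvalidCompositionError(
            "benzyl tag sits on a GalNAc core: hexnac must be >= 1"
        )
    neutral = (
        sum(
            n * permethylated_residue_increment(kind)
            for kind, n in composition.counts().items()
        )
        + WATER_MASS
        + _BENZYL_MINUS_H
        + METHYLENE_MASS
    )
    if adduct == "proton":
        return neutral + PROTON
    if adduct == "sodium":
        return neutral + ELEMENT_MASS["Na"] - ELECTRON
    raise ValueError(f"unknown adduct {adduct!r}; use 'proton' or 'sodium'")


def oxonium_mz(fragment_composition: MonosaccharideComposition) -> float:
    """m/z of the singly charged native oxocarbenium fragment.

    Sum of water-free residue masses plus a proton; e.g. HexNAc -> 204.09,
    HexNAc-Hex -> 366.14, the two diagnostics used to flag glycopeptide
    spectra.
    """
    if fragment_composition.total == 0:
        raise InvalidCompositionError("empty composition has no oxonium ion")
    return (
        sum(
            n * formula_mass(GLYCAN_RESIDUE_FORMULA[kind])
            for kind, n in fragment_composition.counts().items()
        )
        + PROTON
    )


@dataclass(frozen=True)
class GlycanReferenceEntry:
    """One library species: a label, its composition, and its expected m/z."""

    label: str
    composition: MonosaccharideComposition
    expected_mz: float

    def __post_init__(self) -> None:
        if self.expected_mz <= 0:
            raise ValueError("expected_mz must be positive")

    @classmethod
    def from_composition(
        cls, label: str, composition: MonosaccharideComposition, adduct: str = "proton"
    ) -> "GlycanReferenceEntry":
        return cls(label, composition, permethylated_bn_mz(composition, adduct))


@dataclass
class PeakList:
    """A centroided spectrum: parallel m/z / intensity arrays plus metadata."""

    mz: list[float] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    title: str | None = None

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be non-negative")
        order = sorted(range(len(self.mz)), key=lambda i: self.mz[i])
        self.mz = [float(self.mz[i]) for i in order]
        self.intensity = [float(self.intensity[i]) for i in order]

    def __len__(self) -> int:
        return len(self.mz)

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz, self.intensity))


@dataclass(frozen=True)
class GlycanAssignment:
    entry: GlycanReferenceEntry
    matched_mz: float | None
    matched_intensity: float
    relative_abundance: float  # percent; 0 when absent
    absent: bool


@dataclass
class OGlycomeProfile:
    """Per-species relative quantification of an O-glycome spectrum."""

    assignments: list[GlycanAssignment]

    @property
    def matched(self) -> list[GlycanAssignment]:
        return [a for a in self.assignments if not a.absent]

    def abundance(self, label: str) -> float:
        for a in self.assignments:
            if a.entry.label == label:
                return a.relative_abundance
        raise KeyError(label)

    def to_rows(self) -> list[dict]:
        return [
            {
                "label": a.entry.label,
                "composition": str(a.entry.composition),
                "expected_mz": a.entry.expected_mz,
                "matched_mz": a.matched_mz,
                "intensity": a.matched_intensity,
                "relative_abundance_percent": a.relative_abundance,
                "absent": a.absent,
            }
            for a in self.assignments
        ]


def annotate_oglycome(
    peaks: PeakList,
    library: Sequence[GlycanReferenceEntry],
    tolerance: float = 0.3,
) -> OGlycomeProfile:
    """Match each library species to its nearest peak and quantify.

    Each entry takes the single nearest peak within ``tolerance`` Da (ties
    broken by higher intensity, then lower m/z); relative abundance is the
    matched intensity as a percent of the summed matched intensities, so
    assigned abundances always total 100. Unmatched entries are kept with
    zero abundance and flagged absent.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not library:
        raise ValueError("library must be non-empty")
    labels = [e.label for e in library]
    if len(set(labels)) != len(labels):
        raise ValueError("library labels must be unique")

    chosen: list[tuple[GlycanReferenceEntry, float | None, float]] = []
    for entry in sorted(library, key=lambda e: (e.expected_mz, e.label)):
        best: tuple[float, float, float] | None = None  # (|d|, -int, mz)
        for mz, inten in peaks.peaks():
            d = abs(mz - entry.expected_mz)
            if d > tolerance:
                continue
            key = (d, -inten, mz)
            if best is None or key < best:
                best = key
        if best is None:
            chosen.append((entry, None, 0.0))
        else:
            chosen.append((entry, best[2], -best[1]))

    total = sum(inten for _, mz, inten in chosen if mz is not None)
    assignments = []
    for entry, mz, inten in chosen:
        absent = mz is None
        rel = 0.0 if absent or total == 0 else 100.0 * inten / total
        assignments.append(GlycanAssignment(entry, mz, inten, rel, absent))
    return OGlycomeProfile(assignments)


def default_library(adduct: str = "proton") -> list[GlycanReferenceEntry]:
    """The ten-species short-chain O-glycan library of the CORA profile.

    Compositions of the four sialylated/fucosylated core 2 species are fixed
    by residue-increment arithmetic from the printed ion ladder (each differs
    from a neighbour by exactly one Hex, dHex or NeuAc increment).
    """
    C = MonosaccharideComposition
    species = [
        ("Tn", C(hexnac=1)),
        ("T", C(hex=1, hexnac=1)),
        ("STn", C(hexnac=1, neuac=1)),
        ("fucosyl-T", C(hex=1, hexnac=1, dhex=1)),
        ("sialyl-T", C(hex=1, hexnac=1, neuac=1)),
        ("di-sialyl-T", C(hex=1, hexnac=1, neuac=2)),
        ("sialyl-core2", C(hex=1, hexnac=2, neuac=1)),
        ("sialyl-core2-Hex", C(hex=2, hexnac=2, neuac=1)),
        ("fucosyl-sialyl-core2", C(hex=2, hexnac=2, dhex=1, neuac=1)),
        ("di-sialyl-core2", C(hex=2, hexnac=2, neuac=2)),
    ]
    return [GlycanReferenceEntry.from_composition(lbl, c, adduct) for lbl, c in species]


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero, the convention for printed m/z values."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
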