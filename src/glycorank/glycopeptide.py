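"""Glycopeptide-spectrum annotation and O-glycosite localization.

A deterministic, fully specified stand-in for a database search engine:
in-silico proteolysis, candidate glycopeptide generation (HexNAc / Tn and
HexNAc-Hex / T variable modifications on Ser/Thr), fragment matching on
b/y (CID) or b/y/c/z (EThcD) series, oxonium-ion gating, and glycosite
localization by site-determining c/z ions. Scores are matched-ion
fractions with declared confidence tiers, not probabilistic q-values.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import AA_RESIDUE_MASS, AMMONIA_MASS, PROTON, WATER_MASS, formula_mass
from .glyco_mass import MonosaccharideComposition, PeakList, oxonium_mz

__all__ = [
    "ModificationTable",
    "SearchConfig",
    "GlycoPSM",
    "digest",
    "peptide_neutral_mass",
    "theoretical_ions",
    "match_spectrum",
    "localize_glycosite",
    "annotate_spectra",
    "psms_to_dataframe",
    "dataframe_to_psms",
    "GLYCO_MOD_NAMES",
]

GLYCO_MOD_NAMES = frozenset({"HexNAc", "HexNAc-Hex"})

# Oxonium diagnostics, computed (never hard-coded): HexNAc 204.0867,
# HexNAc-Hex 366.1395.
OXONIUM_DIAGNOSTICS = (
    oxonium_mz(MonosaccharideComposition(hexnac=1)),
    oxonium_mz(MonosaccharideComposition(hex=1, hexnac=1)),
)

_HEXNAC_DELTA = formula_mass({"C": 8, "H": 13, "N": 1, "O": 5})
_HEX_DELTA = formula_mass({"C": 6, "H": 10, "O": 5})


class SequenceAlphabetError(ValueError):
    """Sequence contains a letter outside the 20 standard residues."""


class InvalidModificationError(ValueError):
    """A modification placed on a residue it is not allowed on."""


class MissingPrecursorError(ValueError):
    """Spectrum lacks the precursor m/z (and charge) metadata."""


class NoCandidateSiteError(ValueError):
    """Peptide has no Ser/Thr to carry an O-glycan."""


@dataclass(frozen=True)
class ModificationTable:
    """Variable-modification deltas and their allowed residues.

    Defaults mirror a standard O-glycoproteomics search: Met oxidation,
    carbamidomethyl Cys, and HexNAc (+203.1, Tn) / HexNAc-Hex (+365.1, T)
    on Ser/Thr. Deltas are exact monoisotopic masses derived from elemental
    formulas; the one-decimal values are their printed roundings.
    """

    entries: Mapping[str, tuple[float, frozenset[str]]] = field(
        default_factory=lambda: {
            "Oxidation": (formula_mass({"O": 1}), frozenset("M")),
            "Carbamidomethyl": (
                formula_mass({"C": 2, "H": 3, "N": 1, "O": 1}),
                frozenset("C"),
            ),
            "HexNAc": (_HEXNAC_DELTA, frozenset("ST")),
            "HexNAc-Hex": (_HEXNAC_DELTA + _HEX_DELTA, frozenset("ST")),
        }
    )

    def __post_init__(self) -> None:
        for name, (delta, residues) in self.entries.items():
            if delta <= 0:
                raise ValueError(f"modification {name!r}: delta must be > 0")
            if not residues:
                raise ValueError(f"modification {name!r}: no allowed residues")

    def delta(self, name: str) -> float:
        return self.entries[name][0]

    def allowed(self, name: str) -> frozenset[str]:
        return self.entries[name][1]

    def validate(self, peptide: str, modifications: Sequence[tuple[int, str]]) -> None:
        for pos, name in modifications:
            if name not in self.entries:
                raise InvalidModificationError(f"unknown modification {name!r}")
            if not 1 <= pos <= len(peptide):
                raise InvalidModificationError(
                    f"{name} position {pos} outside peptide of length {len(peptide)}"
                )
            if peptide[pos - 1] not in self.allowed(name):
                raise InvalidModificationError(
                    f"{name} not allowed on residue {peptide[pos - 1]!r} at {pos}"
                )


@dataclass(frozen=True)
class SearchConfig:
    """Search-engine settings (precursor ppm, fragment Da, ion series...)."""

    precursor_tol_ppm: float = 5.0
    fragment_tol_da: float = 0.1
    ion_series: frozenset[str] = frozenset({"b", "y", "c", "z"})
    protease: str = "trypsin"
    max_missed_cleavages: int = 2
    max_glycans_per_peptide: int = 3
    min_matched_fraction_high: float = 0.6
    z_dot: bool = True  # z+1 radical ions (EThcD convention)
    min_charge: int = 2
    max_charge: int = 8

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if not self.ion_series:
            raise ValueError("ion_series must be non-empty")
        if not self.ion_series <= {"b", "y", "c", "z"}:
            raise ValueError(f"unknown ion series in {set(self.ion_series)}")

    @classmethod
    def cid(cls, **kw) -> "SearchConfig":
        return cls(ion_series=frozenset({"b", "y"}), **kw)

    @classmethod
    def ethcd(cls, **kw) -> "SearchConfig":
        return cls(ion_series=frozenset({"b", "y", "c", "z"}), **kw)


@dataclass(frozen=True)
class GlycoPSM:
    """One glycopeptide-spectrum match with localization evidence."""

    protein_id: str
    peptide: str
    peptide_interval: tuple[int, int]  # 1-based inclusive in protein
    modifications: tuple[tuple[int, str], ...]  # (1-based position, name)
    matched_fraction: float
    oxonium_present: bool
    localization: str | None  # "unique" | "ambiguous" | None (no glycan)
    candidate_sites: tuple[int, ...]  # 1-based protein coordinates
    confidence: str  # "high" | "medium_low"
    spectrum_title: str | None = None

    @property
    def glyco_modifications(self) -> tuple[tuple[int, str], ...]:
        return tuple((p, n) for p, n in self.modifications if n in GLYCO_MOD_NAMES)

    @property
    def is_glycopeptide(self) -> bool:
        return bool(self.glyco_modifications)


# ---------------------------------------------------------------------------
# Digestion

_CLEAVAGE_RULES = {
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FWYLM"),
}


def digest(
    protein_sequence: str, protease: str = "trypsin", max_missed: int = 0
) -> list[tuple[str, int, int]]:
    """Cleave a protein; return (peptide, start, end) with 1-based intervals.

    Trypsin cuts C-terminal to K/R, chymotrypsin C-terminal to F/W/Y/L/M;
    neither cuts before proline. All products with up to ``max_missed``
    missed cleavages are returned, in N-to-C order.
    """
    seq = protein_sequence.upper()
    bad = set(seq) - set(AA_RESIDUE_MASS)
    if bad:
        raise SequenceAlphabetError(f"illegal residue letters: {sorted(bad)}")
    if protease not in _CLEAVAGE_RULES:
        raise ValueError(f"unknown protease {protease!r}")
    cut_after = _CLEAVAGE_RULES[protease]

    boundaries = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in cut_after and seq[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(seq))

    out: list[tuple[str, int, int]] = []
    for bi in range(len(boundaries) - 1):
        for bj in range(bi + 1, min(bi + 2 + max_missed, len(boundaries))):
            start, end = boundaries[bi], boundaries[bj]
            out.append((seq[start:end], start + 1, end))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


# ---------------------------------------------------------------------------
# Masses and fragment ions

def peptide_neutral_mass(
    peptide: str,
    modifications: Sequence[tuple[int, str]] = (),
    table: ModificationTable | None = None,
) -> float:
    """Monoisotopic neutral mass of a (modified) peptide."""
    table = table or ModificationTable()
    table.validate(peptide, modifications)
    try:
        mass = sum(AA_RESIDUE_MASS[aa] for aa in peptide) + WATER_MASS
    except KeyError as exc:
        raise SequenceAlphabetError(f"illegal residue {exc.args[0]!r}") from exc
    return mass + sum(table.delta(name) for _, name in modifications)


def theoretical_ions(
    peptide: str,
    modifications: Sequence[tuple[int, str]] = (),
    series: Iterable[str] = ("b", "y", "c", "z"),
    table: ModificationTable | None = None,
    z_dot: bool = True,
) -> list[tuple[str, float]]:
    """Singly charged monoisotopic fragment ions for the requested series.

    Conventions: b = prefix + H+; y = suffix + H2O + H+; c = b + NH3;
    z = y − NH3 (z• = z + H by default, the EThcD radical species).
    Fragments span cleavage positions 1..n−1.
    """
    table = table or ModificationTable()
    table.validate(peptide, modifications)
    series = set(series)
    n = len(peptide)
    delta_at = [0.0] * (n + 1)
    for pos, name in modifications:
        delta_at[pos] += table.delta(name)

    prefix = [0.0] * (n + 1)
    for i, aa in enumerate(peptide, start=1):
        prefix[i] = prefix[i - 1] + AA_RESIDUE_MASS[aa] + delta_at[i]
    total = prefix[n]

    z_shift = -AMMONIA_MASS + (formula_mass({"H": 1}) if z_dot else 0.0)
    ions: list[tuple[str, float]] = []
    for i in range(1, n):
        b = prefix[i] + PROTON
        y = total - prefix[i] + WATER_MASS + PROTON
        if "b" in series:
            ions.append((f"b{i}", b))
        if "y" in series:
            ions.append((f"y{n - i}", y))
        if "c" in series:
            ions.append((f"c{i}", b + AMMONIA_MASS))
        if "z" in series:
            ions.append((f"z{n - i}", y + z_shift))
    return ions


def _count_matched(peaks_mz: Sequence[float], targets: Sequence[float], tol: float) -> int:
    matched = 0
    for t in targets:
        lo = bisect_left(peaks_mz, t - tol)
        if lo < len(peaks_mz) and peaks_mz[lo] <= t + tol:
            matched += 1
    return matched


def _has_peak(peaks_mz: Sequence[float], target: float, tol: float) -> bool:
    lo = bisect_left(peaks_mz, target - tol)
    return lo < len(peaks_mz) and peaks_mz[lo] <= target + tol


# ---------------------------------------------------------------------------
# Matching

def match_spectrum(
    peaks: PeakList,
    protein_id: str,
    peptide: str,
    peptide_interval: tuple[int, int],
    modifications: Sequence[tuple[int, str]],
    config: SearchConfig | None = None,
    table: ModificationTable | None = None,
) -> GlycoPSM | None:
    """Score one candidate against one spectrum.

    Returns ``None`` when the precursor is outside the ppm tolerance at
    every accepted charge. The matched fraction is the share of emitted
    theoretical ions found within the fragment tolerance; glyco candidates
    additionally require an oxonium diagnostic peak for high confidence.
    """
    config = config or SearchConfig()
    table = table or ModificationTable()
    if peaks.precursor_mz is None:
        raise MissingPrecursorError("spectrum has no precursor m/z")

    neutral = peptide_neutral_mass(peptide, modifications, table)
    charges = (
        [peaks.precursor_charge]
        if peaks.precursor_charge
        else list(range(config.min_charge, config.max_charge + 1))
    )
    ok = False
    for z in charges:
        observed = (peaks.precursor_mz - PROTON) * z
        if abs(observed - neutral) / neutral * 1e6 <= config.precursor_tol_ppm:
            ok = True
            break
    if not ok:
        return None

    ions = theoretical_ions(
        peptide, modifications, config.ion_series, table, config.z_dot
    )
    targets = [mz for _, mz in ions]
    matched = _count_matched(peaks.mz, targets, config.fragment_tol_da)
    fraction = matched / len(targets) if targets else 0.0

    oxonium = any(
        _has_peak(peaks.mz, d, config.fragment_tol_da) for d in OXONIUM_DIAGNOSTICS
    )
    glyco_positions = tuple(
        p for p, name in modifications if name in GLYCO_MOD_NAMES
    )
    is_glyco = bool(glyco_positions)
    high = fraction >= config.min_matched_fraction_high and (oxonium or not is_glyco)

    start = peptide_interval[0]
    sites = tuple(sorted(start + p - 1 for p in glyco_positions))
    return GlycoPSM(
        protein_id=protein_id,
        peptide=peptide,
        peptide_interval=tuple(peptide_interval),
        modifications=tuple(modifications),
        matched_fraction=fraction,
        oxonium_present=oxonium,
        localization=None,
        candidate_sites=sites,
        confidence="high" if high else "medium_low",
        spectrum_title=peaks.title,
    )


# ---------------------------------------------------------------------------
# Glycosite localization

def _glyco_placements(
    peptide: str, glyco_counts: Mapping[str, int], max_sites: int | None = None
) -> list[tuple[tuple[int, str], ...]]:
    """All distinct placements of a glycan multiset on the peptide's S/T."""
    sites = [i + 1 for i, aa in enumerate(peptide) if aa in "ST"]
    k = sum(glyco_counts.values())
    if not sites:
        raise NoCandidateSiteError(f"peptide {peptide!r} has no S/T")
    if k > len(sites):
        return []
    glycans = [n for n, c in glyco_counts.items() for _ in range(c)]
    placements: set[tuple[tuple[int, str], ...]] = set()
    for chosen in itertools.combinations(sites, k):
        for order in set(itertools.permutations(glycans)):
            placements.add(tuple(sorted(zip(chosen, order))))
    return sorted(placements)


def localize_glycosite(
    psm: GlycoPSM,
    peaks: PeakList,
    config: SearchConfig | None = None,
    table: ModificationTable | None = None,
) -> GlycoPSM:
    """Assign the glycosite(s) by site-determining c/z ion evidence.

    All placements of the PSM's glycan multiset over the peptide's Ser/Thr
    are scored by the number of matched *site-determining* ions — c/z ions
    whose m/z differs between at least two placements. The verdict is
    ``unique`` iff a single placement strictly out-scores all others;
    otherwise ``ambiguous`` with the union of top-scoring placements as the
    candidate site set.
    """
    config = config or SearchConfig()
    table = table or ModificationTable()
    if not psm.is_glycopeptide:
        raise ValueError("localization requires at least one glyco modification")
    if not ({"c", "z"} & config.ion_series):
        raise ValueError("glycosite localization needs c/z ions in ion_series")

    glyco_counts: dict[str, int] = {}
    for _, name in psm.glyco_modifications:
        glyco_counts[name] = glyco_counts.get(name, 0) + 1
    non_glyco = tuple(
        (p, n) for p, n in psm.modifications if n not in GLYCO_MOD_NAMES
    )
    placements = _glyco_placements(psm.peptide, glyco_counts)
    if not placements:
        raise NoCandidateSiteError(
            f"peptide {psm.peptide!r} cannot carry {sum(glyco_counts.values())} glycans"
        )

    cz = config.ion_series & {"c", "z"}
    ion_tables = []
    for placement in placements:
        mods = tuple(sorted(non_glyco + placement))
        ion_tables.append(
            dict(
                theoretical_ions(psm.peptide, mods, cz, table, config.z_dot)
            )
        )

    labels = ion_tables[0].keys()
    site_determining = {
        lbl
        for lbl in labels
        if max(t[lbl] for t in ion_tables) - min(t[lbl] for t in ion_tables) > 1e-9
    }
    scores = [
        sum(
            1
            for lbl in site_determining
            if _has_peak(peaks.mz, t[lbl], config.fragment_tol_da)
        )
        for t in ion_tables
    ]
    if len(placements) == 1:
        best_placements = placements
        verdict = "unique"
    else:
        top = max(scores)
        best_placements = [p for p, s in zip(placements, scores) if s == top]
        verdict = "unique" if len(best_placements) == 1 else "ambiguous"

    start = psm.peptide_interval[0]
    sites = sorted({start + pos - 1 for p in best_placements for pos, _ in p})
    mods = psm.modifications
    if verdict == "unique":
        mods = tuple(sorted(non_glyco + best_placements[0]))
    return replace(
        psm,
        modifications=mods,
        localization=verdict,
        candidate_sites=tuple(sites),
    )


# ---------------------------------------------------------------------------
# Search pipeline

def annotate_spectra(
    proteome: Mapping[str, str],
    spectra: Sequence[PeakList],
    config: SearchConfig | None = None,
    table: ModificationTable | None = None,
    fixed_carbamidomethyl: bool = True,
    min_peptide_length: int = 5,
    max_peptide_length: int = 45,
) -> list[GlycoPSM]:
    """Search spectra against a proteome; one best PSM per matched spectrum.

    Candidates are proteolytic peptides carrying 0..max_glycans HexNAc /
    HexNAc-Hex on Ser/Thr (carbamidomethyl applied as a fixed Cys
    modification by default; Met oxidation is not enumerated). Precursor
    selection is by ppm tolerance over charges ``min_charge..max_charge``
    (or the spectrum's stated charge); each surviving candidate is scored
    over all glycan placements and the best-scoring placement wins. Glyco
    PSMs are then localized when c/z ions are in the configured series.
    """
    config = config or SearchConfig()
    table = table or ModificationTable()

    # (neutral mass, protein, peptide, interval, fixed mods, (nHexNAc, nHexNAcHex))
    candidates: list[tuple[float, str, str, tuple[int, int], tuple, tuple[int, int]]] = []
    seen: set[tuple[str, str, int, int, int, int]] = set()
    d_hexnac = table.delta("HexNAc")
    d_t = table.delta("HexNAc-Hex")
    for pid, seq in proteome.items():
        for pep, start, end in digest(seq, config.protease, config.max_missed_cleavages):
            if not min_peptide_length <= len(pep) <= max_peptide_length:
                continue
            fixed = (
                tuple((i + 1, "Carbamidomethyl") for i, aa in enumerate(pep) if aa == "C")
                if fixed_carbamidomethyl
                else ()
            )
            base = peptide_neutral_mass(pep, fixed, table)
            n_st = sum(aa in "ST" for aa in pep)
            kmax = min(config.max_glycans_per_peptide, n_st)
            for a in range(kmax + 1):
                for b in range(kmax + 1 - a):
                    key = (pid, pep, start, end, a, b)
                    if key in seen:
                        continue
                    seen.add(key)
                    candidates.append(
                        (base + a * d_hexnac + b * d_t, pid, pep, (start, end), fixed, (a, b))
                    )
    candidates.sort(key=lambda c: c[0])
    masses = [c[0] for c in candidates]

    psms: list[GlycoPSM] = []
    for spec in spectra:
        if spec.precursor_mz is None:
            continue
        charges = (
            [spec.precursor_charge]
            if spec.precursor_charge
            else list(range(config.min_charge, config.max_charge + 1))
        )
        best: tuple | None = None  # sort key, psm
        for z in charges:
            observed = (spec.precursor_mz - PROTON) * z
            tol = observed * config.precursor_tol_ppm * 1e-6
            lo = bisect_left(masses, observed - tol)
            hi = bisect_right(masses, observed + tol)
            for mass, pid, pep, interval, fixed, (a, b) in candidates[lo:hi]:
                glyco_counts = {"HexNAc": a, "HexNAc-Hex": b}
                glyco_counts = {k: v for k, v in glyco_counts.items() if v}
                if glyco_counts:
                    placements = _glyco_placements(pep, glyco_counts)
                else:
                    placements = [()]
                for placement in placements:
                    mods = tuple(sorted(fixed + placement))
                    psm = match_spectrum(
                        spec, pid, pep, interval, mods, config, table
                    )
                    if psm is None:
                        continue
                    key = (-psm.matched_fraction, psm.protein_id, psm.peptide, psm.modifications)
                    if best is None or key < best[0]:
                        best = (key, psm)
        if best is None:
            continue
        psm = best[1]
        if psm.is_glycopeptide and ({"c", "z"} & config.ion_series):
            psm = localize_glycosite(psm, spec, config, table)
        psms.append(psm)
    return psms


# ---------------------------------------------------------------------------
# PSM table round-trip

def psms_to_dataframe(psms: Sequence[GlycoPSM]) -> pd.DataFrame:
    rows = []
    for p in psms:
        rows.append(
            {
                "protein_id": p.protein_id,
                "peptide": p.peptide,
                "start": p.peptide_interval[0],
                "end": p.peptide_interval[1],
                "modifications": ";".join(f"{pos}:{name}" for pos, name in p.modifications),
                "matched_fraction": round(p.matched_fraction, 6),
                "oxonium_present": p.oxonium_present,
                "localization": p.localization or "",
                "candidate_sites": ";".join(str(s) for s in p.candidate_sites),
                "confidence": p.confidence,
                "spectrum_title": p.spectrum_title or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "peptide", "start", "end", "modifications",
            "matched_fraction", "oxonium_present", "localization",
            "candidate_sites", "confidence", "spectrum_title",
        ],
    )


def dataframe_to_psms(df: pd.DataFrame) -> list[GlycoPSM]:
    psms = []
    for row in df.to_dict("records"):
        mods = tuple(
            (int(p), n)
            for p, _, n in (
                m.partition(":") for m in str(row["modifications"]).split(";") if m
            )
        )
        sites = tuple(
            int(s) for s in str(row.get("candidate_sites", "")).split(";") if s
        )
        loc = row.get("localization")
        if loc is None or (isinstance(loc, float) and pd.isna(loc)) or str(loc) == "":
            loc = None
        else:
            loc = str(loc)
        psms.append(
            GlycoPSM(
                protein_id=str(row["protein_id"]),
                peptide=str(row["peptide"]),
                peptide_interval=(int(row["start"]), int(row["end"])),
                modifications=mods,
                matched_fraction=float(row["matched_fraction"]),
                oxonium_present=bool(row["oxonium_present"]),
                localization=loc,
                candidate_sites=sites,
                confidence=str(row["confidence"]),
                spectrum_title=str(row.get("spectrum_title") or "") or None,
            )
        )
    return psms
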