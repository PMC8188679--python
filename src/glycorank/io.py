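"""Readers and writers for the plain-text formats the pipeline exchanges.

MGF (Mascot generic format, BEGIN IONS/END IONS blocks), FASTA proteomes
(via Biopython), two-column TSV peak lists, glycan libraries (TSV or JSON),
glyco-PSM tables and cohort tables (TSV via pandas).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .glyco_mass import GlycanReferenceEntry, MonosaccharideComposition, PeakList

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# MGF

def read_mgf(source: PathLike | TextIO) -> list[PeakList]:
    """Parse an MGF file into a list of :class:`PeakList`.

    Honours PEPMASS, CHARGE and TITLE; unknown ``KEY=value`` headers are
    ignored. Charge strings like ``2+`` are accepted.
    """
    if hasattr(source, "read"):
        return list(_parse_mgf(source))
    with open(source) as fh:
        return list(_parse_mgf(fh))


def _parse_mgf(fh: TextIO) -> Iterator[PeakList]:
    in_block = False
    mz: list[float] = []
    inten: list[float] = []
    meta: dict[str, str] = {}
    for raw in fh:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, mz, inten, meta = True, [], [], {}
            continue
        if line == "END IONS":
            if not in_block:
                raise ValueError("END IONS without BEGIN IONS")
            charge = None
            if "CHARGE" in meta:
                charge = int(meta["CHARGE"].rstrip("+").lstrip("-") or 0)
                if meta["CHARGE"].endswith("-"):
                    charge = -charge
            pepmass = None
            if "PEPMASS" in meta:
                pepmass = float(meta["PEPMASS"].split()[0])
            yield PeakList(
                mz=mz,
                intensity=inten,
                precursor_mz=pepmass,
                precursor_charge=charge,
                title=meta.get("TITLE"),
            )
            in_block = False
            continue
        if not in_block:
            continue
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            meta[key.upper()] = value.strip()
        else:
            parts = line.split()
            mz.append(float(parts[0]))
            inten.append(float(parts[1]) if len(parts) > 1 else 1.0)
    if in_block:
        raise ValueError("truncated MGF: BEGIN IONS without END IONS")


def write_mgf(spectra: Iterable[PeakList], path: PathLike) -> None:
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            if spec.title is not None:
                fh.write(f"TITLE={spec.title}\n")
            if spec.precursor_mz is not None:
                fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            if spec.precursor_charge is not None:
                fh.write(f"CHARGE={spec.precursor_charge}+\n")
            for mz, inten in spec.peaks():
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Peak-list TSV (two columns: mz, intensity; header optional)

def read_peaklist_tsv(path: PathLike) -> PeakList:
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                m = float(parts[0])
            except ValueError:
                continue  # header row
            mz.append(m)
            inten.append(float(parts[1]) if len(parts) > 1 else 1.0)
    return PeakList(mz=mz, intensity=inten)


# ---------------------------------------------------------------------------
# Glycan library (TSV: label, hex, hexnac, dhex, neuac; or JSON list)

def read_glycan_library(path: PathLike) -> list[GlycanReferenceEntry]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
    entries = []
    for row in rows:
        comp = MonosaccharideComposition(
            hex=int(row.get("hex", 0)),
            hexnac=int(row.get("hexnac", 0)),
            dhex=int(row.get("dhex", 0)),
            neuac=int(row.get("neuac", 0)),
        )
        if "expected_mz" in row and row["expected_mz"]:
            entries.append(
                GlycanReferenceEntry(str(row["label"]), comp, float(row["expected_mz"]))
            )
        else:
            entries.append(GlycanReferenceEntry.from_composition(str(row["label"]), comp))
    return entries


def write_glycan_library(entries: Sequence[GlycanReferenceEntry], path: PathLike) -> None:
    rows = [
        {
            "label": e.label,
            "hex": e.composition.hex,
            "hexnac": e.composition.hexnac,
            "dhex": e.composition.dhex,
            "neuac": e.composition.neuac,
            "expected_mz": round(e.expected_mz, 4),
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> dict[str, str]:
    """Protein id -> sequence (first whitespace-delimited token of header)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteins: dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tables

def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
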