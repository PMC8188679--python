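"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (config, master seed): it draws from
its own substream (spawned from the master seed with a fixed per-generator
key, so adding a generator never perturbs another's output) and emits the
planted ground truth alongside the data. The stated world follows the
study design the pipeline emulates: a ten-species short-chain O-glycome,
EThcD glycopeptide spectra searched at 5 ppm / 0.1 Da over charge 2+,
tumour-vs-normal expression tables filtered at fold >= 2 and p <= 0.05,
and a ~104-patient bladder-cancer cohort whose stage-wise membrane-
phenotype frequencies reproduce the printed membrane/cytoplasm ratios
(0.07 Ta, 0.38 T1, 0.33 T2, 0.46 T3, 0.63 T4) and whose membrane-positive
hazard is exp(log 3.87) times baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import PROTON
from .glyco_mass import (
    GlycanReferenceEntry,
    MonosaccharideComposition,
    PeakList,
    default_library,
)
from .glycopeptide import (
    GLYCO_MOD_NAMES,
    ModificationTable,
    OXONIUM_DIAGNOSTICS,
    SearchConfig,
    digest,
    peptide_neutral_mass,
    theoretical_ions,
)

__all__ = [
    "SimulationConfig",
    "simulate_oglycome",
    "simulate_proteome",
    "simulate_glycopeptide_spectra",
    "simulate_expression_and_tissues",
    "simulate_cohort",
    "write_truth",
]

# Membrane/cytoplasm ratios printed per stage; converted to membrane-positive
# probabilities among positive cases via r/(1+r).
STAGE_MEMBRANE_RATIO = {"Ta": 0.07, "T1": 0.38, "T2": 0.33, "T3": 0.46, "T4": 0.63}
# metastases: ~60% membrane-positive
_MET_MEMBRANE_PROB = 0.6

# distinct substream keys per generator
_STREAM_KEYS = {
    "oglycome": 11,
    "proteome": 23,
    "spectra": 37,
    "expression": 53,
    "cohort": 71,
}

HEALTHY_TISSUES = (
    "brain", "endocrine", "immune", "muscle", "respiratory", "digestive",
    "urinary_bladder", "kidney", "reproductive", "adipose", "skin",
    "lymphoid", "testis",
)


@dataclass
class SimulationConfig:
    """Stated-world parameters for all generators."""

    seed: int = 0
    # O-glycome
    glycoform_library: list[GlycanReferenceEntry] = field(default_factory=default_library)
    mz_jitter: float = 0.05  # < tolerance/2 at the default 0.3 Da
    noise_peaks_per_spectrum: int = 20
    scan_range: tuple[float, float] = (300.0, 1800.0)
    # proteome / glycopeptide spectra
    n_proteins: int = 50
    protein_length: tuple[int, int] = (120, 360)
    glycosite_density: float = 0.05  # probability an S/T is a planted site
    ion_dropout: float = 0.2
    include_oxonium: bool = True
    fragment_noise_peaks: int = 10
    spectrum_scan_range: tuple[float, float] = (350.0, 1800.0)
    precursor_charge: int = 2
    # expression / tissues
    de_fraction_up: float = 0.1
    planted_fold_range: tuple[float, float] = (2.5, 8.0)
    n_ideal_targets: int = 2
    # cohort
    cohort_size: int = 104
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "Ta": 0.30, "T1": 0.22, "T2": 0.20, "T3": 0.13, "T4": 0.10, "MET": 0.05
        }
    )
    membrane_prob_by_stage: dict[str, float] = field(
        default_factory=lambda: {
            **{s: r / (1.0 + r) for s, r in STAGE_MEMBRANE_RATIO.items()},
            "MET": _MET_MEMBRANE_PROB,
        }
    )
    negative_ihc_prob: float = 0.15
    planted_log_hr: float = math.log(3.87)
    baseline_hazard: float = math.log(2) / 49.0  # median survival ~49 months
    censoring_rate: float = 0.008  # exponential censoring, mean ~125 months
    admin_censor_months: float = 226.0  # longest follow-up in the series
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STREAM_KEYS[stream],))
        )


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# O-glycome spectra

def simulate_oglycome(
    config: SimulationConfig,
    n_species: int | None = None,
    tolerance: float = 0.3,
) -> tuple[PeakList, dict]:
    """One CORA-style profile spectrum: library peaks plus guarded noise.

    Every planted species sits at its theoretical m/z plus a uniform jitter
    below tolerance/2; noise peaks keep at least 2x tolerance away from any
    library m/z so annotation cannot be confounded by construction.
    """
    rng = config.rng("oglycome")
    lib = config.glycoform_library
    if not lib:
        raise ValueError("empty glycoform library")
    n_species = len(lib) if n_species is None else n_species
    chosen = sorted(
        rng.choice(len(lib), size=n_species, replace=False).tolist()
    )
    jitter = rng.uniform(-config.mz_jitter, config.mz_jitter, size=n_species)
    # log-normal intensities, sialylated species boosted to mimic ST dominance
    intensity = rng.lognormal(mean=10.0, sigma=0.8, size=n_species)
    for j, idx in enumerate(chosen):
        if lib[idx].composition.neuac and lib[idx].composition.hex:
            intensity[j] *= 4.0

    mz = [lib[idx].expected_mz + jitter[j] for j, idx in enumerate(chosen)]
    lo, hi = config.scan_range
    guard = 2.0 * tolerance
    noise_mz: list[float] = []
    attempts = 0
    while len(noise_mz) < config.noise_peaks_per_spectrum:
        attempts += 1
        if attempts > 200 * max(1, config.noise_peaks_per_spectrum):
            raise ValueError("library too dense for guarded noise placement")
        x = float(rng.uniform(lo, hi))
        if all(abs(x - e.expected_mz) > guard for e in lib):
            noise_mz.append(x)
    noise_int = rng.lognormal(mean=8.0, sigma=0.5, size=len(noise_mz))

    peaks = PeakList(
        mz=mz + noise_mz,
        intensity=list(intensity) + list(noise_int),
        title=f"oglycome_seed{config.seed}",
    )
    total = float(intensity.sum())
    truth = {
        "kind": "oglycome",
        "seed": config.seed,
        "species": [
            {
                "label": lib[idx].label,
                "mz": lib[idx].expected_mz,
                "intensity": float(intensity[j]),
                "relative_abundance_percent": 100.0 * float(intensity[j]) / total,
            }
            for j, idx in enumerate(chosen)
        ],
    }
    return peaks, truth


# ---------------------------------------------------------------------------
# Proteome and glycopeptide spectra

_AA_BACKGROUND = "ACDEFGHIKLMNPQRVWY"  # S/T placed explicitly


def simulate_proteome(config: SimulationConfig) -> dict[str, str]:
    """Random tryptic-friendly protein sequences with interspersed S/T."""
    rng = config.rng("proteome")
    proteins: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(*config.protein_length))
        letters = []
        for _ in range(length):
            u = rng.random()
            if u < 0.12:
                letters.append("S" if rng.random() < 0.5 else "T")
            elif u < 0.24:
                letters.append("K" if rng.random() < 0.5 else "R")
            else:
                letters.append(_AA_BACKGROUND[int(rng.integers(len(_AA_BACKGROUND)))])
        proteins[f"GP{i:04d}"] = "".join(letters)
    return proteins


def simulate_glycopeptide_spectra(
    config: SimulationConfig,
    proteome: dict[str, str],
    search_config: SearchConfig | None = None,
) -> tuple[list[PeakList], dict]:
    """EThcD-style spectra for planted glycosites, with dropout and noise.

    For each protein, fully tryptic peptides (no missed cleavages, length
    6-30, with at least one S/T) are scanned; each S/T becomes a planted
    site with probability ``glycosite_density`` (at most one glycopeptide
    per peptide; one glycan per planted site, Tn or T at a coin flip). The
    spectrum holds the complete singly charged b/y/c/z ladder of the
    modified peptide minus independent per-ion dropout, the oxonium
    diagnostics, and noise peaks kept 2x fragment tolerance away from every
    placement hypothesis' ions. The precursor is exact at the configured
    charge, well within 5 ppm.
    """
    rng = config.rng("spectra")
    search_config = search_config or SearchConfig()
    table = ModificationTable()
    spectra: list[PeakList] = []
    truth_records: list[dict] = []

    for pid in sorted(proteome):
        seq = proteome[pid]
        for pep, start, end in digest(seq, "trypsin", max_missed=0):
            if not 6 <= len(pep) <= 30:
                continue
            st_positions = [i + 1 for i, aa in enumerate(pep) if aa in "ST"]
            if not st_positions:
                continue
            planted = [p for p in st_positions if rng.random() < config.glycosite_density]
            if not planted:
                continue
            site = int(planted[int(rng.integers(len(planted)))])
            glycan = "HexNAc" if rng.random() < 0.5 else "HexNAc-Hex"
            # samples are alkylated before digestion: Cys carries a fixed
            # carbamidomethyl, matching the search engine's assumption
            fixed = tuple(
                (i + 1, "Carbamidomethyl") for i, aa in enumerate(pep) if aa == "C"
            )
            mods = tuple(sorted(fixed + ((site, glycan),)))

            ions = theoretical_ions(pep, mods, ("b", "y", "c", "z"), table,
                                    search_config.z_dot)
            # skip degenerate plantings: if some rival placement's every
            # site-determining c/z ion falls within the fragment tolerance of
            # a true ion, the site is unlocalizable in principle (isobaric
            # interference), which is not what these spectra are for
            if _is_degenerate(
                pep, fixed, glycan, site, st_positions, ions, table,
                search_config,
            ):
                continue
            keep = [
                (lbl, mzv) for lbl, mzv in ions if rng.random() >= config.ion_dropout
            ]
            mz = [m for _, m in keep]
            inten = list(rng.lognormal(mean=9.0, sigma=0.4, size=len(mz)))
            if config.include_oxonium:
                for d in OXONIUM_DIAGNOSTICS:
                    mz.append(d)
                    inten.append(float(rng.lognormal(mean=11.0, sigma=0.3)))

            # noise avoiding every placement hypothesis' c/z and b/y ions
            avoid: list[float] = []
            for alt in st_positions:
                avoid.extend(
                    m
                    for _, m in theoretical_ions(
                        pep, tuple(sorted(fixed + ((alt, glycan),))),
                        ("b", "y", "c", "z"), table, search_config.z_dot,
                    )
                )
            avoid.extend(OXONIUM_DIAGNOSTICS)
            guard = 2.0 * search_config.fragment_tol_da
            lo, hi = config.spectrum_scan_range
            added = 0
            attempts = 0
            while added < config.fragment_noise_peaks and attempts < 2000:
                attempts += 1
                x = float(rng.uniform(lo, hi))
                if all(abs(x - a) > guard for a in avoid):
                    mz.append(x)
                    inten.append(float(rng.lognormal(mean=7.0, sigma=0.5)))
                    added += 1

            z = config.precursor_charge
            neutral = peptide_neutral_mass(pep, mods, table)
            title = f"{pid}|{start}-{end}|{pep}"
            spectra.append(
                PeakList(
                    mz=mz,
                    intensity=inten,
                    precursor_mz=neutral / z + PROTON,
                    precursor_charge=z,
                    title=title,
                )
            )
            truth_records.append(
                {
                    "spectrum_title": title,
                    "protein_id": pid,
                    "peptide": pep,
                    "peptide_start": start,
                    "peptide_end": end,
                    "site_in_peptide": site,
                    "site_in_protein": start + site - 1,
                    "glycan": glycan,
                    "n_candidate_sites": len(st_positions),
                }
            )
    truth = {
        "kind": "glycopeptide_spectra",
        "seed": config.seed,
        "ion_dropout": config.ion_dropout,
        "spectra": truth_records,
    }
    return spectra, truth


def _is_degenerate(
    pep: str,
    fixed: tuple,
    glycan: str,
    site: int,
    st_positions: list[int],
    true_ions: list[tuple[str, float]],
    table: ModificationTable,
    search_config: SearchConfig,
) -> bool:
    """True when a rival glycosite placement cannot lose to the planted one.

    With the complete true ion ladder present, the planted placement matches
    all of its site-determining c/z ions; a rival stays distinguishable only
    if at least one of its site-determining ions misses every true ion by
    more than the fragment tolerance.
    """
    if len(st_positions) == 1:
        return False
    cz = {"c", "z"} & set(search_config.ion_series) or {"c", "z"}
    tables = {
        alt: dict(
            theoretical_ions(
                pep, tuple(sorted(fixed + ((alt, glycan),))), sorted(cz),
                table, search_config.z_dot,
            )
        )
        for alt in st_positions
    }
    labels = tables[st_positions[0]].keys()
    sdi = [
        lbl for lbl in labels
        if max(t[lbl] for t in tables.values()) - min(t[lbl] for t in tables.values()) > 1e-9
    ]
    true_mzs = sorted(m for _, m in true_ions) + list(OXONIUM_DIAGNOSTICS)
    tol = search_config.fragment_tol_da
    for alt in st_positions:
        if alt == site:
            continue
        rival_all_matched = all(
            any(abs(tables[alt][lbl] - m) <= tol for m in true_mzs) for lbl in sdi
        )
        if rival_all_matched:
            return True
    return False


# ---------------------------------------------------------------------------
# Expression table and tissue matrix

def simulate_expression_and_tissues(
    config: SimulationConfig, gene_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Tumour-vs-normal DE table plus an atlas-style tissue matrix.

    A seeded fraction of genes is planted up-regulated (fold and p safely
    past the 2-fold / 0.05 thresholds); the rest straddle the thresholds
    (some pass one criterion but not both). The first ``n_ideal_targets``
    planted genes also receive an ideal-target tissue profile: negative in
    every healthy tissue including the urothelium, membrane-localized,
    prognosis-associated, no lymphoid/gamete expression — the profile that
    maximizes the target score.
    """
    rng = config.rng("expression")
    if gene_ids is None:
        gene_ids = [f"GP{i:04d}" for i in range(config.n_proteins)]
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    n_up = max(1, int(round(config.de_fraction_up * n)))
    up_idx = sorted(rng.choice(n, size=n_up, replace=False).tolist())
    up_set = set(up_idx)

    lo_f, hi_f = config.planted_fold_range
    ideal_idx = set(up_idx[: config.n_ideal_targets])
    rows = []
    for i, gid in enumerate(gene_ids):
        if i in up_set:
            fold = float(rng.uniform(lo_f, hi_f))
            p = float(10 ** rng.uniform(-8.0, -2.0))
            # ideal targets are up in both NMIBC and MIBC (max DE points)
            cohort = (
                "both" if i in ideal_idx or rng.random() < 0.5 else "MIBC"
            )
        else:
            arm = rng.random()
            if arm < 0.4:  # clearly not changed
                fold = float(rng.uniform(0.4, 1.6))
                p = float(rng.uniform(0.05, 1.0))
            elif arm < 0.7:  # fold passes, p fails
                fold = float(rng.uniform(2.0, 5.0))
                p = float(rng.uniform(0.051, 0.6))
            else:  # p passes, fold fails
                fold = float(rng.uniform(1.0, 1.99))
                p = float(10 ** rng.uniform(-5.0, -1.4))
                p = min(p, 0.05)
            cohort = "MIBC"
        rows.append(
            {"gene_id": gid, "fold_change": round(fold, 3),
             "p_value": float(f"{p:.3g}"), "cohort": cohort}
        )
    de_table = pd.DataFrame(rows)

    ideal = [gene_ids[i] for i in up_idx[: config.n_ideal_targets]]
    levels = ("negative", "low", "moderate", "high")
    tissue_rows = []
    for i, gid in enumerate(gene_ids):
        if gid in ideal:
            profile = {t: "negative" for t in HEALTHY_TISSUES}
            extra = {
                "tumour_percent_positive": float(rng.integers(85, 101)),
                "subcellular_cancer": "plasma_membrane",
                "prognosis_association": True,
                "lymphoid_or_gamete_expression": False,
            }
        else:
            profile = {
                t: levels[int(rng.choice(4, p=[0.25, 0.3, 0.25, 0.2]))]
                for t in HEALTHY_TISSUES
            }
            extra = {
                "tumour_percent_positive": float(rng.integers(0, 101)),
                "subcellular_cancer": (
                    "plasma_membrane" if rng.random() < 0.4 else "other"
                ),
                "prognosis_association": bool(rng.random() < 0.3),
                "lymphoid_or_gamete_expression": bool(rng.random() < 0.3),
            }
        tissue_rows.append({"gene_id": gid, **profile, **extra})
    tissue_matrix = pd.DataFrame(tissue_rows)

    truth = {
        "kind": "expression",
        "seed": config.seed,
        "planted_up_genes": [gene_ids[i] for i in up_idx],
        "planted_folds": {
            gene_ids[i]: rows[i]["fold_change"] for i in up_idx
        },
        "ideal_targets": ideal,
    }
    return de_table, tissue_matrix, truth


# ---------------------------------------------------------------------------
# Patient cohort

def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """A bladder-cancer cohort with a planted membrane-phenotype hazard.

    Stage is drawn from ``stage_distribution``; among IHC-positive cases
    the membrane phenotype is Bernoulli with the stage's probability
    (defaults derived from the printed membrane/cytoplasm ratios). Survival
    is exponential with hazard ``baseline * exp(planted_log_hr)`` for
    membrane-positive patients, censored by an independent exponential
    clock and an administrative cap at the longest follow-up.
    """
    if config.cohort_size < 20:
        raise ValueError("cohort_size must be at least 20")
    rng = config.rng("cohort")
    stages = list(config.stage_distribution)
    probs = np.array([config.stage_distribution[s] for s in stages], float)
    probs /= probs.sum()

    rows = []
    for i in range(config.cohort_size):
        stage = stages[int(rng.choice(len(stages), p=probs))]
        negative = rng.random() < config.negative_ihc_prob
        if negative:
            membrane = False
            intensity, extension, location = 0, 0, "negative"
        else:
            membrane = rng.random() < config.membrane_prob_by_stage.get(stage, 0.3)
            intensity = int(rng.integers(1, 4))
            extension = int(rng.integers(1, 11)) * 10
            location = "membrane_and_cytoplasm" if membrane else "cytoplasm"
        grade = "high" if stage != "Ta" or rng.random() < 0.25 else "low"

        hazard = config.baseline_hazard * math.exp(
            config.planted_log_hr if membrane else 0.0
        )
        if config.survival_model == "weibull":
            k = config.weibull_shape
            scale = hazard ** (-1.0 / k)
            t_death = float(scale * rng.weibull(k))
        else:
            t_death = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.exponential(1.0 / config.censoring_rate))
        followup = min(t_death, t_censor, config.admin_censor_months)
        event = t_death <= min(t_censor, config.admin_censor_months)
        rows.append(
            {
                "patient_id": f"P{i:04d}",
                "stage": stage,
                "grade": grade,
                "intensity": intensity,
                "extension": extension,
                "location": location,
                "followup_months": round(followup, 3),
                "event": int(event),
            }
        )
    cohort = pd.DataFrame(rows)
    truth = {
        "kind": "cohort",
        "seed": config.seed,
        "planted_log_hr": config.planted_log_hr,
        "planted_hazard_ratio": math.exp(config.planted_log_hr),
        "membrane_prob_by_stage": dict(config.membrane_prob_by_stage),
        "n_membrane_positive": int(
            (cohort["location"] == "membrane_and_cytoplasm").sum()
        ),
        "n_events": int(cohort["event"].sum()),
    }
    return cohort, truth
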