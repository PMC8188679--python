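"""Protein-level curation and biomarker prioritization (the target score).

Aggregates glycopeptide-spectrum matches per protein, applies the curation
rule (one high-confidence glycopeptide, or two or more distinct
medium/low-confidence glycopeptides), annotates candidates with
differential-expression status and tissue-atlas expression bins, and ranks
them by a 0-15 point target score that rewards tumour overexpression,
plasma-membrane localization and absence from healthy tissues while
penalizing expression in lymphoid organs and gametes.

The rubric is this package's declared point allocation (the published
system is qualitative with a stated maximum of 15); every weight is exposed
in :class:`ScoreRubric` so alternative allocations are drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .glycopeptide import GlycoPSM

__all__ = [
    "ProteinCandidate",
    "DEFilter",
    "ScoreRubric",
    "EXPRESSION_BINS",
    "TISSUE_LEVELS",
    "curate_proteins",
    "venn_counts",
    "apply_de_filter",
    "bin_tumour_expression",
    "annotate_tissue_profile",
    "ANNOTATION_COLUMNS",
    "target_score",
    "rank_candidates",
    "candidates_to_dataframe",
]

#: Tumour expression bins (percent of patients expressing the protein).
EXPRESSION_BINS = ("high", "moderate", "low", "negative", "unknown")

#: Healthy-tissue expression levels, atlas-style.
TISSUE_LEVELS = ("high", "moderate", "low", "negative", "not_available")

DE_STATUSES = ("up_both", "up_MIBC", "not_up", "unknown")


@dataclass(frozen=True)
class DEFilter:
    """Differential-expression thresholds: linear fold >= 2 and p <= 0.05."""

    min_fold: float = 2.0
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if not 0 < self.max_p < 1:
            raise ValueError("max_p must be in (0, 1)")

    def passes(self, fold_change: float, p_value: float) -> bool:
        # boundary-inclusive on both thresholds
        return fold_change >= self.min_fold and p_value <= self.max_p


@dataclass
class ProteinCandidate:
    """Per-protein glyco-evidence plus expression annotations and score."""

    protein_id: str
    cell_lines_detected: frozenset[str] = frozenset()
    glyco_psms: tuple[GlycoPSM, ...] = ()
    curated: bool = False
    de_status: str = "unknown"
    fold_change: float | None = None
    p_value: float | None = None
    tumour_expression_bin: str = "unknown"
    healthy_tissue_profile: dict[str, str] = field(default_factory=dict)
    subcellular_cancer: str = "other"  # "plasma_membrane" | "other"
    prognosis_association: bool = False
    lymphoid_or_gamete_expression: bool = False
    target_score: int | None = None

    def __post_init__(self) -> None:
        if self.de_status not in DE_STATUSES:
            raise ValueError(f"unknown de_status {self.de_status!r}")
        if self.tumour_expression_bin not in EXPRESSION_BINS:
            raise ValueError(
                f"unknown tumour_expression_bin {self.tumour_expression_bin!r}"
            )
        for tissue, level in self.healthy_tissue_profile.items():
            if level not in TISSUE_LEVELS:
                raise ValueError(f"unknown tissue level {level!r} for {tissue!r}")

    @property
    def distinct_glycopeptides(self) -> int:
        return len({p.peptide for p in self.glyco_psms})


# ---------------------------------------------------------------------------
# Curation

def curate_proteins(psms: Sequence[GlycoPSM]) -> list[ProteinCandidate]:
    """Group PSMs by protein and apply the glycopeptide-evidence rule.

    A protein is curated (retained) when it has at least one
    high-confidence glyco PSM, or at least two distinct medium/low
    glycopeptide *sequences* (multiplicity counts peptides, not spectra).
    Non-glyco PSMs contribute nothing to curation.
    """
    by_protein: dict[str, list[GlycoPSM]] = {}
    for psm in psms:
        if not psm.is_glycopeptide:
            continue
        by_protein.setdefault(psm.protein_id, []).append(psm)

    out = []
    for pid in sorted(by_protein):
        plist = by_protein[pid]
        high = [p for p in plist if p.confidence == "high"]
        medlow_peptides = {p.peptide for p in plist if p.confidence != "high"}
        curated = bool(high) or len(medlow_peptides) >= 2
        out.append(
            ProteinCandidate(
                protein_id=pid, glyco_psms=tuple(plist), curated=curated
            )
        )
    return out


# ---------------------------------------------------------------------------
# Venn arithmetic

def venn_counts(per_source_sets: Mapping[str, Iterable[str]]) -> dict:
    """Exact set arithmetic over per-source identification sets.

    Returns union and intersection sizes, per-source exclusive counts, and
    the shared fraction |intersection| / |union| rounded to the nearest
    whole percent.
    """
    if len(per_source_sets) < 2:
        raise ValueError("need at least two sources")
    sets = {k: frozenset(v) for k, v in per_source_sets.items()}
    union = frozenset().union(*sets.values())
    inter = frozenset.intersection(*sets.values())
    exclusive = {
        k: len(s - frozenset().union(*(o for kk, o in sets.items() if kk != k)))
        for k, s in sets.items()
    }
    percent = round(100 * len(inter) / len(union)) if union else 0
    return {
        "sizes": {k: len(s) for k, s in sets.items()},
        "union": len(union),
        "intersection": len(inter),
        "exclusive": exclusive,
        "percent_shared": percent,
    }


# ---------------------------------------------------------------------------
# Expression annotation

def apply_de_filter(
    candidates: Sequence[ProteinCandidate],
    de_table: pd.DataFrame,
    de_filter: DEFilter | None = None,
) -> list[ProteinCandidate]:
    """Annotate candidates with up-regulation status from a DE table.

    The table needs columns ``gene_id``, ``fold_change``, ``p_value`` and
    optionally ``cohort`` (``MIBC`` or ``both``). A candidate passes when
    fold >= min_fold AND p <= max_p (boundary-inclusive); ids absent from
    the table become ``unknown``.
    """
    de_filter = de_filter or DEFilter()
    required = {"gene_id", "fold_change", "p_value"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table lacks columns {sorted(missing)}")

    rows: dict[str, dict] = {}
    for i, row in enumerate(de_table.to_dict("records")):
        try:
            gid = str(row["gene_id"])
            fc = float(row["fold_change"])
            p = float(row["p_value"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed DE table row {i + 2}: {exc}") from exc
        if not 0 <= p <= 1 or fc < 0:
            raise ValueError(
                f"malformed DE table row {i + 2}: fold={fc}, p={p} out of domain"
            )
        rows[gid] = {"fold": fc, "p": p, "cohort": str(row.get("cohort", "MIBC"))}

    out = []
    for cand in candidates:
        row = rows.get(cand.protein_id)
        if row is None:
            out.append(replace(cand, de_status="unknown",
                               fold_change=None, p_value=None))
            continue
        if de_filter.passes(row["fold"], row["p"]):
            status = "up_both" if row["cohort"] == "both" else "up_MIBC"
        else:
            status = "not_up"
        out.append(
            replace(cand, de_status=status,
                    fold_change=row["fold"], p_value=row["p"])
        )
    return out


def bin_tumour_expression(percent_positive_patients: float | None) -> str:
    """Bin percent-of-positive-patients into high/moderate/low/negative.

    80-100% -> high; 40-79% -> moderate; 1-39% -> low; 0% -> negative;
    missing -> unknown. The partition follows the printed cut points, with
    non-integer percentages assigned to the bin whose range contains them.
    """
    if percent_positive_patients is None:
        return "unknown"
    p = float(percent_positive_patients)
    if p != p:  # NaN
        return "unknown"
    if not 0 <= p <= 100:
        raise ValueError(f"percent {p} outside [0, 100]")
    if p >= 80:
        return "high"
    if p >= 40:
        return "moderate"
    if p >= 1:
        return "low"
    if p == 0:
        return "negative"
    return "low"  # (0, 1): trace positivity counts as low


#: Non-tissue columns a protein-annotation table may carry alongside the
#: healthy-tissue categories.
ANNOTATION_COLUMNS = (
    "tumour_percent_positive",
    "subcellular_cancer",
    "prognosis_association",
    "lymphoid_or_gamete_expression",
)


def annotate_tissue_profile(
    candidates: Sequence[ProteinCandidate],
    tissue_matrix: pd.DataFrame,
) -> list[ProteinCandidate]:
    """Attach healthy-tissue levels and any extra annotation columns.

    Every column other than ``gene_id`` and the recognised
    :data:`ANNOTATION_COLUMNS` is treated as a healthy tissue with an
    atlas-style category value. The optional annotation columns set the
    tumour expression bin (from percent positive patients), cancer
    subcellular location, prognosis association and the lymphoid/gamete
    flag. Proteins absent from the table get an all-``not_available``
    profile and worst-case annotations.
    """
    if "gene_id" not in tissue_matrix.columns:
        raise ValueError("tissue matrix lacks a gene_id column")
    tissues = [
        c for c in tissue_matrix.columns
        if c != "gene_id" and c not in ANNOTATION_COLUMNS
    ]
    records = {str(r["gene_id"]): r for r in tissue_matrix.to_dict("records")}
    out = []
    for cand in candidates:
        row = records.get(cand.protein_id)
        if row is None:
            out.append(
                replace(
                    cand,
                    healthy_tissue_profile={t: "not_available" for t in tissues},
                )
            )
            continue
        updated = replace(
            cand, healthy_tissue_profile={t: str(row[t]) for t in tissues}
        )
        if "tumour_percent_positive" in row:
            pct = row["tumour_percent_positive"]
            pct = None if pd.isna(pct) else float(pct)
            updated = replace(updated, tumour_expression_bin=bin_tumour_expression(pct))
        if "subcellular_cancer" in row:
            updated = replace(updated, subcellular_cancer=str(row["subcellular_cancer"]))
        if "prognosis_association" in row:
            updated = replace(
                updated, prognosis_association=bool(row["prognosis_association"])
            )
        if "lymphoid_or_gamete_expression" in row:
            updated = replace(
                updated,
                lymphoid_or_gamete_expression=bool(row["lymphoid_or_gamete_expression"]),
            )
        out.append(updated)
    return out


# ---------------------------------------------------------------------------
# Target score

#: Per-tissue burden weight of healthy expression; higher is worse for a
#: therapeutic target. Missing data is scored worst-case.
_TISSUE_BURDEN = {
    "high": 1.0,
    "moderate": 0.6,
    "low": 0.3,
    "negative": 0.0,
    "not_available": 1.0,
}


@dataclass(frozen=True)
class ScoreRubric:
    """Declared point allocation of the 0-15 target score.

    Components sum to 15: healthy-tissue absence (0-5), absence from the
    healthy urothelium (0-2), tumour expression bin (0-3), plasma-membrane
    localization in cancer (0-2), prognosis association (0-1), and
    transcriptomic up-regulation (0-2); lymphoid/gamete expression then
    subtracts 3 points and the total is clamped to [0, 15]. Unknown
    annotations always score worst case.
    """

    healthy_tissue_max: int = 5
    urothelium_points: Mapping[str, int] = field(
        default_factory=lambda: {
            "negative": 2, "low": 1, "moderate": 0, "high": 0, "not_available": 0
        }
    )
    tumour_bin_points: Mapping[str, int] = field(
        default_factory=lambda: {
            "high": 3, "moderate": 2, "low": 1, "negative": 0, "unknown": 0
        }
    )
    membrane_points: int = 2
    prognosis_points: int = 1
    de_points: Mapping[str, int] = field(
        default_factory=lambda: {"up_both": 2, "up_MIBC": 1, "not_up": 0, "unknown": 0}
    )
    lymphoid_gamete_penalty: int = 3
    urothelium_tissue: str = "urinary_bladder"

    @property
    def maximum(self) -> int:
        return (
            self.healthy_tissue_max
            + max(self.urothelium_points.values())
            + max(self.tumour_bin_points.values())
            + self.membrane_points
            + self.prognosis_points
            + max(self.de_points.values())
        )

    def healthy_tissue_points(self, profile: Mapping[str, str]) -> int:
        """0..healthy_tissue_max, graded down by breadth/level of expression.

        The burden is the mean per-tissue weight (high 1.0, moderate 0.6,
        low 0.3, negative 0, missing treated as worst case); an empty
        profile scores 0 (no evidence of absence).
        """
        others = {t: lv for t, lv in profile.items() if t != self.urothelium_tissue}
        if not others:
            return 0
        burden = sum(_TISSUE_BURDEN[lv] for lv in others.values()) / len(others)
        pts = int(self.healthy_tissue_max * (1.0 - burden) + 0.5)
        return max(0, min(self.healthy_tissue_max, pts))


def target_score(
    candidate: ProteinCandidate, rubric: ScoreRubric | None = None
) -> int:
    """Compute the 0-15 target score for one annotated candidate."""
    rubric = rubric or ScoreRubric()
    profile = candidate.healthy_tissue_profile
    urothelium = profile.get(rubric.urothelium_tissue, "not_available")
    score = (
        rubric.healthy_tissue_points(profile)
        + rubric.urothelium_points[urothelium]
        + rubric.tumour_bin_points[candidate.tumour_expression_bin]
        + (rubric.membrane_points if candidate.subcellular_cancer == "plasma_membrane" else 0)
        + (rubric.prognosis_points if candidate.prognosis_association else 0)
        + rubric.de_points[candidate.de_status]
    )
    if candidate.lymphoid_or_gamete_expression:
        score -= rubric.lymphoid_gamete_penalty
    return max(0, min(15, score))


def rank_candidates(
    candidates: Sequence[ProteinCandidate],
    rubric: ScoreRubric | None = None,
    require_tumour_data: bool = False,
) -> list[ProteinCandidate]:
    """Score and order candidates: descending score, then tumour bin, then id.

    ``require_tumour_data`` restricts the ranking to candidates with a known
    tumour expression bin (mirroring a ranking limited to proteins with
    tumour IHC data).
    """
    rubric = rubric or ScoreRubric()
    pool = [
        c for c in candidates
        if not require_tumour_data or c.tumour_expression_bin != "unknown"
    ]
    scored = [replace(c, target_score=target_score(c, rubric)) for c in pool]
    bin_order = {b: i for i, b in enumerate(EXPRESSION_BINS)}
    scored.sort(
        key=lambda c: (
            -c.target_score,
            bin_order[c.tumour_expression_bin],
            c.protein_id,
        )
    )
    return scored


def candidates_to_dataframe(candidates: Sequence[ProteinCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "protein_id": c.protein_id,
                "target_score": c.target_score if c.target_score is not None else "",
                "curated": c.curated,
                "distinct_glycopeptides": c.distinct_glycopeptides,
                "de_status": c.de_status,
                "fold_change": "" if c.fold_change is None else round(c.fold_change, 4),
                "p_value": "" if c.p_value is None else f"{c.p_value:.3g}",
                "tumour_expression_bin": c.tumour_expression_bin,
                "subcellular_cancer": c.subcellular_cancer,
                "prognosis_association": c.prognosis_association,
                "lymphoid_or_gamete_expression": c.lymphoid_or_gamete_expression,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "target_score", "curated", "distinct_glycopeptides",
            "de_status", "fold_change", "p_value", "tumour_expression_bin",
            "subcellular_cancer", "prognosis_association",
            "lymphoid_or_gamete_expression",
        ],
    )
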