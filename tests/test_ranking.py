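"""Curation rule, Venn arithmetic, DE filter, expression bins, target score."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycorank.glycopeptide import GlycoPSM
from glycorank.ranking import (
    DEFilter,
    ProteinCandidate,
    ScoreRubric,
    annotate_tissue_profile,
    apply_de_filter,
    bin_tumour_expression,
    curate_proteins,
    rank_candidates,
    target_score,
    venn_counts,
)
from glycorank.simulate import HEALTHY_TISSUES


def _psm(protein, peptide, confidence, glycan="HexNAc"):
    site = next(i + 1 for i, aa in enumerate(peptide) if aa in "ST")
    return GlycoPSM(
        protein_id=protein,
        peptide=peptide,
        peptide_interval=(1, len(peptide)),
        modifications=((site, glycan),),
        matched_fraction=0.9 if confidence == "high" else 0.3,
        oxonium_present=confidence == "high",
        localization="unique",
        candidate_sites=(site,),
        confidence=confidence,
    )


class TestCuration:
    def test_one_medium_low_peptide_excluded(self):
        out = curate_proteins([_psm("A", "SAK", "medium_low")])
        assert len(out) == 1 and not out[0].curated

    def test_two_distinct_medium_low_peptides_retained(self):
        out = curate_proteins(
            [_psm("A", "SAK", "medium_low"), _psm("A", "TGGK", "medium_low")]
        )
        assert out[0].curated

    def test_one_high_confidence_peptide_retained(self):
        out = curate_proteins([_psm("A", "SAK", "high")])
        assert out[0].curated

    def test_multiplicity_counts_peptides_not_spectra(self):
        # same peptide sequence seen in three spectra is still multiplicity 1
        psms = [_psm("A", "SAK", "medium_low") for _ in range(3)]
        out = curate_proteins(psms)
        assert not out[0].curated
        assert out[0].distinct_glycopeptides == 1

    def test_empty_input(self):
        assert curate_proteins([]) == []


class TestVennCounts:
    def test_printed_cell_line_overlap(self):
        """607 + 553 with 257 shared -> union 903, 28% common."""
        a = {f"p{i}" for i in range(607)}
        b = {f"p{i}" for i in range(350, 903)}  # |b|=553, overlap 257
        assert len(a & b) == 257
        out = venn_counts({"T24": a, "5637": b})
        assert out["union"] == 903
        assert out["intersection"] == 257
        assert out["percent_shared"] == 28

    def test_identical_sets_fully_shared(self):
        out = venn_counts({"a": {"x", "y"}, "b": {"x", "y"}})
        assert out["percent_shared"] == 100
        assert out["exclusive"] == {"a": 0, "b": 0}

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.sets(st.integers(0, 200), max_size=80),
        b=st.sets(st.integers(0, 200), max_size=80),
    )
    def test_inclusion_exclusion(self, a, b):
        if not (a | b):
            return
        out = venn_counts({"a": {str(x) for x in a}, "b": {str(x) for x in b}})
        assert out["sizes"]["a"] + out["sizes"]["b"] - out["intersection"] == out["union"]


class TestDEFilter:
    @pytest.fixture
    def candidates(self):
        return [ProteinCandidate(protein_id=p) for p in ("A", "B", "C")]

    def test_boundary_inclusive_and_below_threshold(self, candidates):
        table = pd.DataFrame(
            {
                "gene_id": ["A", "B"],
                "fold_change": [2.0, 1.9],
                "p_value": [0.05, 0.001],
            }
        )
        out = apply_de_filter(candidates, table)
        status = {c.protein_id: c.de_status for c in out}
        assert status["A"] == "up_MIBC"  # fold 2.0, p 0.05 passes on the boundary
        assert status["B"] == "not_up"  # fold 1.9 fails despite tiny p
        assert status["C"] == "unknown"  # absent from the table

    def test_cohort_column_sets_up_both(self, candidates):
        table = pd.DataFrame(
            {
                "gene_id": ["A"],
                "fold_change": [3.0],
                "p_value": [0.01],
                "cohort": ["both"],
            }
        )
        out = apply_de_filter(candidates[:1], table)
        assert out[0].de_status == "up_both"

    def test_malformed_row_reported_with_position(self, candidates):
        table = pd.DataFrame(
            {"gene_id": ["A"], "fold_change": ["oops"], "p_value": [0.1]}
        )
        with pytest.raises(ValueError, match="row 2"):
            apply_de_filter(candidates, table)


class TestExpressionBinning:
    @pytest.mark.parametrize(
        "percent,expected",
        [
            (100, "high"), (85, "high"), (80, "high"),
            (79, "moderate"), (40, "moderate"),
            (39, "low"), (1, "low"),
            (0, "negative"),
            (None, "unknown"),
        ],
    )
    def test_printed_partition(self, percent, expected):
        assert bin_tumour_expression(percent) == expected

    @pytest.mark.parametrize("percent", [-1, 101])
    def test_domain_error(self, percent):
        with pytest.raises(ValueError):
            bin_tumour_expression(percent)


# ---------------------------------------------------------------------------
# Target score

TISSUE_SUBSET = ("brain", "digestive", "lymphoid")  # reduced lattice for enumeration
LEVELS = ("negative", "low", "moderate", "high")
BIN_ORDER = ("negative", "unknown", "low", "moderate", "high")
DE_ORDER = ("unknown", "not_up", "up_MIBC", "up_both")


def _candidate(tissues, urothelium, tumour_bin, membrane, prognosis, de, penalty):
    profile = dict(zip(TISSUE_SUBSET, tissues))
    profile["urinary_bladder"] = urothelium
    return ProteinCandidate(
        protein_id="X",
        healthy_tissue_profile=profile,
        tumour_expression_bin=tumour_bin,
        subcellular_cancer="plasma_membrane" if membrane else "other",
        prognosis_association=prognosis,
        de_status=de,
        lymphoid_or_gamete_expression=penalty,
    )


def _lattice():
    for tissues in itertools.product(LEVELS, repeat=len(TISSUE_SUBSET)):
        for urothelium in LEVELS:
            for tumour_bin in BIN_ORDER:
                for membrane in (False, True):
                    for prognosis in (False, True):
                        for de in DE_ORDER:
                            for penalty in (True, False):
                                yield (tissues, urothelium, tumour_bin,
                                       membrane, prognosis, de, penalty)


class TestTargetScore:
    def test_ideal_candidate_scores_maximum_15(self):
        best = _candidate(
            ("negative",) * 3, "negative", "high", True, True, "up_both", False
        )
        assert target_score(best) == 15
        assert ScoreRubric().maximum == 15

    def test_worst_candidate_scores_0(self):
        worst = _candidate(
            ("high",) * 3, "high", "unknown", False, False, "unknown", True
        )
        assert target_score(worst) == 0

    def test_lattice_bounds_and_maximum(self):
        """Exhaustive enumeration: scores stay in [0, 15] and attain both ends."""
        scores = {target_score(_candidate(*point)) for point in _lattice()}
        assert min(scores) == 0
        assert max(scores) == 15
        assert all(0 <= s <= 15 for s in scores)

    def test_monotone_in_every_attribute(self):
        """Improving any single attribute never decreases the score."""
        lvl = {l: i for i, l in enumerate(LEVELS)}  # lower index = better
        bins = {b: i for i, b in enumerate(BIN_ORDER)}  # higher = better
        de = {d: i for i, d in enumerate(DE_ORDER)}
        for point in _lattice():
            tissues, uro, tbin, mem, prog, destat, pen = point
            s = target_score(_candidate(*point))
            # improve one tissue by one level
            for i, t in enumerate(tissues):
                if lvl[t] > 0:
                    better = list(tissues)
                    better[i] = LEVELS[lvl[t] - 1]
                    assert target_score(
                        _candidate(tuple(better), uro, tbin, mem, prog, destat, pen)
                    ) >= s
            if lvl[uro] > 0:
                assert target_score(
                    _candidate(tissues, LEVELS[lvl[uro] - 1], tbin, mem, prog, destat, pen)
                ) >= s
            if bins[tbin] < len(BIN_ORDER) - 1:
                assert target_score(
                    _candidate(tissues, uro, BIN_ORDER[bins[tbin] + 1], mem, prog, destat, pen)
                ) >= s
            if not mem:
                assert target_score(_candidate(tissues, uro, tbin, True, prog, destat, pen)) >= s
            if not prog:
                assert target_score(_candidate(tissues, uro, tbin, mem, True, destat, pen)) >= s
            if de[destat] < len(DE_ORDER) - 1:
                assert target_score(
                    _candidate(tissues, uro, tbin, mem, prog, DE_ORDER[de[destat] + 1], pen)
                ) >= s
            if pen:
                assert target_score(_candidate(tissues, uro, tbin, mem, prog, destat, False)) >= s

    def test_calibration_fixtures_reproduce_published_totals(self):
        """Synthetic attribute vectors expressing the published example scores
        (top targets 13, a mucin 10, a stemness marker 5) under this rubric."""
        full = lambda level: {t: level for t in HEALTHY_TISSUES if t != "urinary_bladder"}
        top = ProteinCandidate(  # 4 + 2 + 3 + 2 + 1 + 1 = 13
            protein_id="HOMER3",
            healthy_tissue_profile={**full("negative"), "brain": "high",
                                    "endocrine": "low",
                                    "urinary_bladder": "negative"},
            tumour_expression_bin="high",
            subcellular_cancer="plasma_membrane",
            prognosis_association=True,
            de_status="up_MIBC",
        )
        assert target_score(top) == 13
        mucin = ProteinCandidate(  # 2 + 2 + 3 + 2 + 1 + 0 = 10
            protein_id="MUC16",
            healthy_tissue_profile={**full("moderate"), "urinary_bladder": "negative"},
            tumour_expression_bin="high",
            subcellular_cancer="plasma_membrane",
            prognosis_association=True,
            de_status="not_up",
        )
        assert target_score(mucin) == 10
        ubiquitous = ProteinCandidate(  # 0 + 0 + 3 + 2 + 0 + 0 = 5
            protein_id="CD44",
            healthy_tissue_profile={**full("high"), "urinary_bladder": "high"},
            tumour_expression_bin="high",
            subcellular_cancer="plasma_membrane",
            prognosis_association=False,
            de_status="not_up",
        )
        assert target_score(ubiquitous) == 5


class TestRanking:
    def test_tie_break_by_bin_then_id(self):
        a = _candidate(("negative",) * 3, "negative", "high", True, True, "up_both", False)
        b = ProteinCandidate(**{**a.__dict__, "protein_id": "B"})
        a = ProteinCandidate(**{**a.__dict__, "protein_id": "A"})
        c = _candidate(("high",) * 3, "high", "low", False, False, "unknown", False)
        c = ProteinCandidate(**{**c.__dict__, "protein_id": "C"})
        ranked = rank_candidates([c, b, a])
        assert [r.protein_id for r in ranked] == ["A", "B", "C"]

    def test_empty_input(self):
        assert rank_candidates([]) == []

    def test_permutation_invariance(self):
        import random

        cands = [
            _candidate(t, u, b, m, p, d, pen)
            for (t, u, b, m, p, d, pen) in itertools.islice(_lattice(), 0, 2000, 37)
        ]
        for i, c in enumerate(cands):
            cands[i] = ProteinCandidate(**{**c.__dict__, "protein_id": f"P{i:03d}"})
        base = [c.protein_id for c in rank_candidates(cands)]
        rng = random.Random(5)
        for _ in range(3):
            shuffled = cands[:]
            rng.shuffle(shuffled)
            assert [c.protein_id for c in rank_candidates(shuffled)] == base

    def test_require_tumour_data_restricts_pool(self):
        known = _candidate(("low",) * 3, "low", "high", True, False, "unknown", False)
        unknown = _candidate(("low",) * 3, "low", "unknown", True, False, "unknown", False)
        ranked = rank_candidates([known, unknown], require_tumour_data=True)
        assert len(ranked) == 1
        assert ranked[0].tumour_expression_bin == "high"


class TestTissueAnnotation:
    def test_profile_and_extra_columns_applied(self):
        matrix = pd.DataFrame(
            [
                {
                    "gene_id": "A",
                    "brain": "negative",
                    "urinary_bladder": "negative",
                    "tumour_percent_positive": 90.0,
                    "subcellular_cancer": "plasma_membrane",
                    "prognosis_association": True,
                    "lymphoid_or_gamete_expression": False,
                }
            ]
        )
        out = annotate_tissue_profile([ProteinCandidate(protein_id="A")], matrix)
        c = out[0]
        assert c.healthy_tissue_profile == {"brain": "negative", "urinary_bladder": "negative"}
        assert c.tumour_expression_bin == "high"
        assert c.subcellular_cancer == "plasma_membrane"
        assert c.prognosis_association

    def test_missing_protein_gets_not_available(self):
        matrix = pd.DataFrame([{"gene_id": "A", "brain": "high"}])
        out = annotate_tissue_profile([ProteinCandidate(protein_id="Z")], matrix)
        assert out[0].healthy_tissue_profile == {"brain": "not_available"}
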