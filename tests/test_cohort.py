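"""IHC scoring, association tests, Kaplan-Meier/log-rank, Cox regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from glycorank.cohort import (
    CohortRecord,
    DegenerateTableError,
    IHCReading,
    association_test,
    cohort_from_dataframe,
    cox_fit,
    ihc_score,
    km_curve,
    km_logrank,
    membrane_cytoplasm_ratio,
)


def _rec(pid, stage, location, followup, event, grade="high", intensity=2, ext=50):
    if location == "negative":
        intensity, ext = 0, 0
    return CohortRecord(
        patient_id=pid,
        stage=stage,
        grade=grade,
        ihc=IHCReading(intensity=intensity, extension_percent=ext, location=location),
        followup_months=followup,
        event=event,
    )


class TestIHCScore:
    @pytest.mark.parametrize(
        "intensity,extension,expected",
        [(3, 100, 30), (0, 0, 0), (2, 50, 10), (1, 10, 1), (3, 70, 21)],
    )
    def test_intensity_times_extension_tenths(self, intensity, extension, expected):
        loc = "negative" if intensity == 0 else "cytoplasm"
        assert ihc_score(IHCReading(intensity, extension, loc)) == expected

    @pytest.mark.parametrize(
        "intensity,extension",
        [(4, 50), (2, 55), (0, 50), (2, 0)],
    )
    def test_invalid_readings_rejected(self, intensity, extension):
        with pytest.raises(ValueError):
            IHCReading(intensity, extension, "cytoplasm")


class TestMembraneCytoplasmRatio:
    def test_hand_counts(self):
        cohort = (
            [_rec(f"m{i}", "T4", "membrane_and_cytoplasm", 10, False) for i in range(7)]
            + [_rec(f"c{i}", "T4", "cytoplasm", 10, False) for i in range(11)]
        )
        out = membrane_cytoplasm_ratio(cohort)
        assert out["T4"] == pytest.approx(7 / 11)

    def test_zero_membrane_is_zero(self):
        cohort = [_rec("c0", "Ta", "cytoplasm", 5, False)]
        assert membrane_cytoplasm_ratio(cohort)["Ta"] == 0.0

    def test_zero_cytoplasm_is_undefined(self):
        cohort = [_rec("m0", "T1", "membrane_and_cytoplasm", 5, False)]
        assert membrane_cytoplasm_ratio(cohort)["T1"] is None

    def test_negative_cases_excluded(self):
        cohort = [
            _rec("m0", "T2", "membrane_and_cytoplasm", 5, False),
            _rec("c0", "T2", "cytoplasm", 5, False),
            _rec("n0", "T2", "negative", 5, False),
        ]
        assert membrane_cytoplasm_ratio(cohort)["T2"] == 1.0


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by minimum-likelihood over all tables with the
    observed margins (independent oracle)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestAssociationTest:
    def test_perfect_independence(self):
        stat, p, method = association_test([[10, 10], [10, 10]])
        assert method == "chi2"
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_auto_selects_fisher_below_5(self):
        _, p, method = association_test([[1, 9], [8, 2]])
        assert method == "fisher"
        assert p == pytest.approx(_fisher_enumeration(1, 9, 8, 2), abs=1e-12)

    def test_auto_selection_boundary_is_exactly_5(self):
        assert association_test([[5, 5], [5, 5]])[2] == "chi2"
        assert association_test([[4, 6], [5, 5]])[2] == "fisher"

    def test_chi2_matches_pearson_hand_formula(self):
        table = np.array([[50, 50], [90, 10]], float)
        stat, p, method = association_test(table.astype(int))
        assert method == "chi2"
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        hand = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(hand, abs=1e-12)
        assert p < 0.001

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            association_test([[0, 0], [5, 5]])


class TestKaplanMeier:
    def test_hand_worked_curve_and_restricted_mean(self):
        # 3 subjects: events at 1 and 2, censored at 3
        curve = km_curve([1, 2, 3], [True, True, False])
        assert list(curve.times) == [1, 2]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3])
        # RMST = 1*1 + (2-1)*2/3 + (3-2)*1/3
        assert curve.restricted_mean == pytest.approx(2.0)
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(2.5) == pytest.approx(1 / 3)

    def test_curve_non_increasing_from_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(50, size=60)
        e = rng.random(60) < 0.6
        curve = km_curve(t, e)
        s = [1.0] + list(curve.survival)
        assert all(s[i + 1] <= s[i] for i in range(len(s) - 1))
        assert all(0 <= x <= 1 for x in s)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        t = rng.exponential(60, size=80).round(1)
        e = rng.random(80) < 0.7
        mine = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for x in (5, 20, 60, 120):
            assert mine.survival_at(x) == pytest.approx(float(kmf.predict(x)), abs=1e-10)


class TestLogRank:
    def test_hand_worked_risk_set_table(self):
        """3 subjects per group; O-E and variance tabulated by hand:
        statistic = (0.5)^2 / (7/12) = 3/7."""
        groups = {
            "A": [
                _rec("a1", "T1", "cytoplasm", 1, True),
                _rec("a2", "T1", "cytoplasm", 2, True),
                _rec("a3", "T1", "cytoplasm", 3, False),
            ],
            "B": [
                _rec("b1", "T1", "cytoplasm", 1, False),
                _rec("b2", "T1", "cytoplasm", 2, True),
                _rec("b3", "T1", "cytoplasm", 4, True),
            ],
        }
        fit = km_logrank(groups)
        assert fit.logrank_statistic == pytest.approx(3 / 7, abs=1e-9)

    def test_identical_groups_give_zero(self):
        g = [
            _rec("a", "T1", "cytoplasm", 5, True),
            _rec("b", "T1", "cytoplasm", 9, True),
        ]
        fit = km_logrank({"x": g, "y": list(g)})
        assert fit.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        ga = [_rec(f"a{i}", "T1", "cytoplasm", t, True) for i, t in enumerate([2, 5, 9, 13])]
        gb = [_rec(f"b{i}", "T1", "cytoplasm", t, e)
              for i, (t, e) in enumerate([(1, True), (4, False), (7, True), (20, True)])]
        s1 = km_logrank({"a": ga, "b": gb}).logrank_statistic
        s2 = km_logrank({"a": gb, "b": ga}).logrank_statistic
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_all_censored_flags_undefined(self):
        ga = [_rec("a", "T1", "cytoplasm", 5, False)]
        gb = [_rec("b", "T1", "cytoplasm", 8, False)]
        fit = km_logrank({"a": ga, "b": gb})
        assert fit.logrank_statistic is None and fit.logrank_p is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"a": [], "b": [_rec("b", "T1", "cytoplasm", 8, True)]})

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(21)
        ta = rng.exponential(40, 30).round(2)
        tb = rng.exponential(70, 35).round(2)
        ea, eb = rng.random(30) < 0.7, rng.random(35) < 0.7
        ga = [_rec(f"a{i}", "T1", "cytoplasm", t, bool(e)) for i, (t, e) in enumerate(zip(ta, ea))]
        gb = [_rec(f"b{i}", "T1", "cytoplasm", t, bool(e)) for i, (t, e) in enumerate(zip(tb, eb))]
        fit = km_logrank({"a": ga, "b": gb})
        ref = logrank_test(ta, tb, ea, eb)
        assert fit.logrank_statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert fit.logrank_p == pytest.approx(ref.p_value, rel=1e-9)


def _grid_partial_loglik(beta, t, e, x):
    """Brute-force Cox partial log-likelihood (tie-free data, Breslow form)."""
    ll = 0.0
    for i in range(len(t)):
        if not e[i]:
            continue
        risk = [j for j in range(len(t)) if t[j] >= t[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    T = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    E = [True, True, False, True, True, True, False, True]
    X = [1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0]

    def test_coefficient_matches_grid_search(self):
        res = cox_fit(self.T, self.E, self.X)
        grid = np.linspace(-4, 4, 160001)
        lls = [_grid_partial_loglik(b, self.T, self.E, self.X) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert res.coefficients[0] == pytest.approx(best, abs=1e-4)
        assert res.converged

    def test_constant_covariate_is_uninformative(self):
        res = cox_fit(self.T, self.E, [1.0] * 8)
        assert res.hazard_ratios[0] == pytest.approx(1.0)
        assert res.p_values[0] == pytest.approx(1.0)

    def test_efron_equals_breslow_without_ties(self):
        a = cox_fit(self.T, self.E, self.X, ties="efron")
        b = cox_fit(self.T, self.E, self.X, ties="breslow")
        assert a.coefficients[0] == pytest.approx(b.coefficients[0], abs=1e-10)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(17)
        n = 120
        x = (rng.random(n) < 0.4).astype(float)
        t = np.ceil(rng.exponential(30 / np.exp(0.8 * x)))  # integer ties
        e = rng.random(n) < 0.75
        res = cox_fit(t, e, x)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert res.coefficients[0] == pytest.approx(ref.params_["x"], abs=1e-6)
        assert res.standard_errors[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-6)

    def test_monotone_likelihood_flagged(self):
        # perfect separation: all events in one arm, none in the other
        t = [1, 2, 3, 4, 10, 11, 12, 13]
        e = [True] * 4 + [False] * 4
        x = [1.0] * 4 + [0.0] * 4
        res = cox_fit(t, e, x)
        assert (not res.converged) or abs(res.coefficients[0]) > 10
        if not res.converged:
            assert res.message != ""

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2], [False, False], [0.0, 1.0])


class TestCohortTable:
    def test_round_trip_through_dataframe(self):
        df = pd.DataFrame(
            [
                {"patient_id": "P1", "stage": "T2", "grade": "high",
                 "intensity": 2, "extension": 60, "location": "cytoplasm",
                 "followup_months": 48.5, "event": 1},
                {"patient_id": "P2", "stage": "Ta", "grade": "low",
                 "intensity": 0, "extension": 0, "location": "negative",
                 "followup_months": 120.0, "event": 0},
            ]
        )
        records = cohort_from_dataframe(df)
        assert records[0].event and records[0].stage == "T2"
        assert ihc_score(records[0].ihc) == 12
        assert not records[1].event and records[1].ihc.intensity == 0
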