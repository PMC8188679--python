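"""Cohort-level IHC scoring and association/survival statistics.

Implements, from their defining formulas: the semi-quantitative IHC score
(intensity 0-3 x staining extension in 10% cut-offs, range 0-30), the
membrane/cytoplasm phenotype ratio by tumour stage, Pearson chi-square and
Fisher exact association tests with the cells-below-5 auto-selection rule,
the Kaplan-Meier product-limit estimator with a multi-group log-rank test,
and Cox proportional-hazards regression by Newton-Raphson on the Efron
partial likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IHCReading",
    "CohortRecord",
    "SurvivalFit",
    "CoxResult",
    "ihc_score",
    "membrane_cytoplasm_ratio",
    "association_test",
    "km_curve",
    "km_logrank",
    "cox_fit",
    "cohort_from_dataframe",
]

STAGES = ("Ta", "T1", "T2", "T3", "T4", "MET")
LOCATIONS = ("cytoplasm", "membrane_and_cytoplasm", "negative")


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin carries no association information."""


@dataclass(frozen=True)
class IHCReading:
    """One immunohistochemistry reading: intensity, extension, location."""

    intensity: int  # 0 negative, 1 weak, 2 moderate, 3 strong
    extension_percent: int  # stained area, recorded in 10% cut-offs
    location: str  # cytoplasm | membrane_and_cytoplasm | negative

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be 0-3, got {self.intensity}")
        if not 0 <= self.extension_percent <= 100 or self.extension_percent % 10:
            raise ValueError(
                f"extension must be a multiple of 10 in [0, 100], got {self.extension_percent}"
            )
        if (self.intensity == 0) != (self.extension_percent == 0):
            raise ValueError("intensity 0 iff extension 0")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if (self.location == "negative") != (self.intensity == 0):
            raise ValueError("location 'negative' iff intensity 0")


@dataclass(frozen=True)
class CohortRecord:
    """One patient: stage, grade, IHC phenotype, follow-up and outcome."""

    patient_id: str
    stage: str
    grade: str  # low | high
    ihc: IHCReading
    followup_months: float
    event: bool  # death by cancer during follow-up

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.grade not in ("low", "high"):
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.followup_months < 0:
            raise ValueError("follow-up must be non-negative")

    @property
    def membrane_positive(self) -> bool:
        return self.ihc.location == "membrane_and_cytoplasm"


def ihc_score(reading: IHCReading) -> int:
    """Intensity (0-3) times extension in tenths (0-10): integer 0-30."""
    return reading.intensity * (reading.extension_percent // 10)


def membrane_cytoplasm_ratio(
    cohort: Sequence[CohortRecord],
) -> dict[str, float | None]:
    """Per-stage ratio of membrane-positive to cytoplasm-only cases.

    Only antigen-positive cases enter; a stage with no cytoplasm-only cases
    yields ``None`` (undefined), never infinity. Stages absent from the
    cohort are omitted.
    """
    out: dict[str, float | None] = {}
    for stage in STAGES:
        records = [r for r in cohort if r.stage == stage and r.ihc.location != "negative"]
        if not records:
            continue
        mem = sum(r.ihc.location == "membrane_and_cytoplasm" for r in records)
        cyt = sum(r.ihc.location == "cytoplasm" for r in records)
        out[stage] = None if cyt == 0 else mem / cyt
    return out


# ---------------------------------------------------------------------------
# Association tests

def association_test(
    table: Sequence[Sequence[int]], method: str = "auto"
) -> tuple[float | None, float, str]:
    """Test independence in a 2x2 table; returns (statistic, p, method used).

    ``auto`` selects Fisher's exact test when any observed cell is below 5,
    otherwise the Pearson chi-square (no continuity correction by default).
    Fisher p-values are two-sided by the minimum-likelihood rule; the Fisher
    statistic slot carries the conditional odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("a zero margin makes the test degenerate")

    if method == "auto":
        method = "fisher" if t.min() < 5 else "chi2"
    if method == "fisher":
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return float(odds), float(p), "fisher"
    if method == "chi2":
        n = t.sum()
        expected = np.outer(row, col) / n
        statistic = float(((t - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(statistic, df=1))
        return statistic, p, "chi2"
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

@dataclass
class KMCurve:
    """Right-continuous non-increasing step function starting at 1."""

    times: np.ndarray  # event times where the curve steps
    survival: np.ndarray  # S(t) immediately after each step
    n_subjects: int
    n_events: int
    restricted_mean: float  # integral of S up to the largest observed time

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimator with right censoring, plus restricted mean."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty group")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    step_t: list[float] = []
    step_s: list[float] = []
    s = 1.0
    n_at_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        d = 0
        removed = 0
        while i < len(times) and times[i] == t:
            d += int(events[i])
            removed += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            step_t.append(t)
            step_s.append(s)
        n_at_risk -= removed

    # restricted mean survival time: area under S(t) on [0, max observed]
    tau = float(times[-1])
    rmst = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, sv in zip(step_t, step_s):
        rmst += prev_s * (t - prev_t)
        prev_t, prev_s = t, sv
    rmst += prev_s * (tau - prev_t)
    return KMCurve(
        times=np.asarray(step_t),
        survival=np.asarray(step_s),
        n_subjects=len(times),
        n_events=int(events.sum()),
        restricted_mean=rmst,
    )


@dataclass
class SurvivalFit:
    """Grouped KM curves plus the log-rank comparison."""

    curves: dict[str, KMCurve]
    logrank_statistic: float | None
    logrank_p: float | None
    df: int

    @property
    def group_means(self) -> dict[str, float]:
        return {g: c.restricted_mean for g, c in self.curves.items()}


def km_logrank(groups: Mapping[str, Sequence[CohortRecord]]) -> SurvivalFit:
    """Kaplan-Meier per group and the k-sample log-rank test.

    The statistic sums observed-minus-expected events over the distinct
    event times of the pooled sample; p comes from chi-square with
    (groups - 1) degrees of freedom. With no events anywhere the fit is
    returned with the statistic and p flagged undefined (None).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, recs in groups.items():
        if not recs:
            raise ValueError(f"group {g!r} has no subjects")

    names = sorted(groups)
    curves = {
        g: km_curve(
            [r.followup_months for r in groups[g]],
            [r.event for r in groups[g]],
        )
        for g in names
    }

    times = {g: np.asarray([r.followup_months for r in groups[g]], float) for g in names}
    events = {g: np.asarray([r.event for r in groups[g]], bool) for g in names}
    all_event_times = np.unique(
        np.concatenate([times[g][events[g]] for g in names])
    )
    k = len(names)
    if all_event_times.size == 0:
        return SurvivalFit(curves, None, None, k - 1)

    # observed and expected events per group (first k-1 groups suffice)
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k - 1, k - 1))
    for t in all_event_times:
        n_g = np.array([(times[g] >= t).sum() for g in names], float)
        d_g = np.array(
            [((times[g] == t) & events[g]).sum() for g in names], float
        )
        n_tot, d_tot = n_g.sum(), d_g.sum()
        if n_tot == 0 or d_tot == 0:
            continue
        observed += d_g
        expected += d_tot * n_g / n_tot
        if n_tot > 1:
            frac = n_g[:-1] / n_tot
            cov = (
                d_tot
                * (n_tot - d_tot)
                / (n_tot - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
            var += cov
    diff = (observed - expected)[:-1]
    try:
        statistic = float(diff @ np.linalg.solve(var, diff))
    except np.linalg.LinAlgError:
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return SurvivalFit(curves, statistic, p, k - 1)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)

@dataclass
class CoxResult:
    """Cox fit summary: per-covariate HR, SE, Wald p, and diagnostics."""

    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    covariates: tuple[str, ...]
    log_likelihood: float
    converged: bool
    n_iterations: int
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "se": self.standard_errors,
                "p": self.p_values,
            }
        )


def _cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    groups: list[tuple[np.ndarray, np.ndarray]],
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron/Breslow partial log-likelihood with gradient and Hessian.

    ``groups`` holds, per distinct event time, (risk-set row indices,
    tied-event row indices).
    """
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for risk_idx, tied_idx in groups:
        d = len(tied_idx)
        s0_r = w[risk_idx].sum()
        s1_r = (w[risk_idx, None] * X[risk_idx]).sum(axis=0)
        s2_r = (w[risk_idx, None, None] * X[risk_idx, :, None] * X[risk_idx, None, :]).sum(axis=0)
        ll += eta[tied_idx].sum()
        grad += X[tied_idx].sum(axis=0)
        if ties == "efron" and d > 1:
            s0_t = w[tied_idx].sum()
            s1_t = (w[tied_idx, None] * X[tied_idx]).sum(axis=0)
            s2_t = (w[tied_idx, None, None] * X[tied_idx, :, None] * X[tied_idx, None, :]).sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = s0_r - f * s0_t
                s1 = s1_r - f * s1_t
                s2 = s2_r - f * s2_t
                ll -= math.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        else:  # breslow, or a single event
            ll -= d * math.log(s0_r)
            grad -= d * s1_r / s0_r
            hess -= d * (s2_r / s0_r - np.outer(s1_r, s1_r) / s0_r**2)
    return ll, grad, hess


def cox_fit(
    durations: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame | np.ndarray,
    ties: str = "efron",
    max_iterations: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Efron tie handling by default (``ties="breslow"`` available).
    Convergence when the relative change of the partial log-likelihood
    drops below ``tol``; non-convergence or a monotone likelihood (runaway
    coefficients) is flagged on the result, never silent.
    """
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not e.any():
        raise ValueError("no events: partial likelihood is undefined")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")

    # center covariates for numerical stability (shift leaves beta unchanged);
    # constant columns carry no information and are excluded from the fit
    constant = np.ptp(X, axis=0) == 0
    if constant.all():
        n = X.shape[1]
        return CoxResult(
            np.zeros(n), np.ones(n), np.full(n, np.inf), np.ones(n),
            names, 0.0, True, 0, "all covariates constant: no information",
        )
    keep = ~constant
    Xc = (X - X.mean(axis=0))[:, keep]

    groups = []
    for et in np.unique(t[e]):
        risk_idx = np.nonzero(t >= et)[0]
        tied_idx = np.nonzero((t == et) & e)[0]
        groups.append((risk_idx, tied_idx))

    beta = np.zeros(Xc.shape[1])
    ll_prev, grad, hess = _cox_loglik(beta, Xc, groups, ties)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iterations + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian (collinear covariates?)"
            break
        candidate = beta - step
        ll_new, grad_new, hess_new = _cox_loglik(candidate, Xc, groups, ties)
        # step-halving if the likelihood decreases
        halvings = 0
        while ll_new < ll_prev and halvings < 20:
            step /= 2.0
            candidate = beta - step
            ll_new, grad_new, hess_new = _cox_loglik(candidate, Xc, groups, ties)
            halvings += 1
        beta, grad, hess = candidate, grad_new, hess_new
        if np.any(np.abs(beta) > 50):
            message = "monotone likelihood: coefficient diverging"
            break
        if abs(ll_new - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            ll_prev = ll_new
            converged = True
            break
        ll_prev = ll_new

    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se_fit = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se_fit = np.full(Xc.shape[1], np.nan)
    # scatter fitted columns back; constant columns get HR 1, p 1
    beta_full = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    beta_full[keep] = beta
    se[keep] = se_fit
    with np.errstate(all="ignore"):
        zscores = np.where(np.isinf(se), 0.0, beta_full / se)
    pvals = 2.0 * stats.norm.sf(np.abs(zscores))
    return CoxResult(
        coefficients=beta_full,
        hazard_ratios=np.exp(beta_full),
        standard_errors=se,
        p_values=pvals,
        covariates=names,
        log_likelihood=ll_prev,
        converged=converged,
        n_iterations=it,
        message=message,
    )


# ---------------------------------------------------------------------------
# Cohort table I/O

def cohort_from_dataframe(df: pd.DataFrame) -> list[CohortRecord]:
    required = {
        "patient_id", "stage", "grade", "intensity", "extension",
        "location", "followup_months", "event",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                stage=str(row["stage"]),
                grade=str(row["grade"]),
                ihc=IHCReading(
                    intensity=int(row["intensity"]),
                    extension_percent=int(row["extension"]),
                    location=str(row["location"]),
                ),
                followup_months=float(row["followup_months"]),
                event=bool(int(row["event"])),
            )
        )
    return records
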