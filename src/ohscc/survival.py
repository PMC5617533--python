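"""Outcome analysis: Kaplan-Meier, log-rank cutoffs, Cox, composite score.

The prognostic procedure dichotomizes each candidate variable at the cutoff
that maximizes the log-rank statistic over the cohort (maximally selected
log-rank), enters the dichotomized variables into Cox proportional-hazards
models, and condenses the independent risk factors into a composite score:
each factor present contributes 1 point, for a total of 0-4.  Score strata
are compared by Kaplan-Meier curves, an overall log-rank test, and
per-stratum hazard ratios against the worst stratum as reference.

Kaplan-Meier estimation, log-rank testing and Cox regression are backed by
``lifelines`` (Efron tie handling for the month-resolution ties typical of
survival tables); the cutoff search, risk definitions, scoring and
stratified reporting are implemented here.

Note the selection bias inherent in maximally selected cutoffs: the log-rank
p-value at the selected cutoff is optimistic and no multiplicity correction
is applied, mirroring common radiomics practice; reports carry a caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

SELECTION_BIAS_CAVEAT = (
    "Cutoffs were selected by maximizing the log-rank statistic; the "
    "associated p-values are optimistic (no multiplicity correction)."
)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray      # distinct observed times (events and censorings)
    survival: np.ndarray   # S(t) immediately after each time
    max_time: float
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) by step evaluation; see module-level :func:`survival_at`."""
        return survival_at(self, t)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KmCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        max_time=float(times.max()),
        n=int(times.size),
    )


def survival_at(curve: KmCurve, t_months: float) -> float:
    """Evaluate S(t); warns when t exceeds follow-up (last value carried)."""
    if t_months < 0:
        raise ValueError("t must be nonnegative")
    if t_months > curve.max_time:
        warnings.warn(
            f"t = {t_months} exceeds the observed follow-up ({curve.max_time}); "
            "carrying the last estimate forward",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t_months, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p) with k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Maximally selected log-rank cutoff
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Outcome of the exhaustive log-rank cutoff scan for one variable."""

    variable: str
    cutoff: float
    high_risk_side: str          # 'le' (low values risky) or 'gt'
    statistic: float
    p: float
    n_candidates: int
    caveat: str = SELECTION_BIAS_CAVEAT


def _restricted_mean(times, events) -> float:
    curve = km_estimate(times, events)
    # area under the KM step function up to the last observed time
    t = np.concatenate([[0.0], curve.times, [curve.max_time]])
    s = np.concatenate([[1.0], curve.survival, [curve.survival[-1]]])
    return float(np.sum(np.diff(t) * s[:-1]))


def find_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_frac: float = 0.1,
    variable: str = "variable",
) -> CutoffResult:
    """Exhaustive log-rank scan over candidate dichotomization cutoffs.

    Candidates are the midpoints between consecutive distinct order
    statistics; splits leaving either group below ``min_group_frac * n``
    are excluded (0 disables the guard).  The cutoff maximizing the
    log-rank chi-square is returned; ties break toward the smaller cutoff.
    The risky side is the group with the smaller restricted mean survival.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError(f"{variable} is constant; no cutoff exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_size = min_group_frac * n
    best = None
    n_admissible = 0
    for c in candidates:
        low = values <= c
        n_low = int(low.sum())
        if n_low < min_size or (n - n_low) < min_size:
            continue
        n_admissible += 1
        stat, p = logrank_test([(times[low], events[low]), (times[~low], events[~low])])
        if best is None or stat > best[0] + 1e-12:
            best = (stat, p, c)
    if best is None:
        raise ValueError(
            f"no admissible cutoff for {variable} under min_group_frac={min_group_frac}"
        )
    stat, p, cutoff = best
    low = values <= cutoff
    rm_low = _restricted_mean(times[low], events[low])
    rm_high = _restricted_mean(times[~low], events[~low])
    side = "le" if rm_low < rm_high else "gt"
    return CutoffResult(
        variable=variable, cutoff=float(cutoff), high_risk_side=side,
        statistic=stat, p=p, n_candidates=n_admissible,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def fit_cox(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
) -> pd.DataFrame:
    """Cox PH fit (Efron ties); per-covariate HR, 95% CI and Wald p.

    Raises on constant covariates or non-convergence with diagnostics.
    """
    covariates = pd.DataFrame(covariates).astype(float)
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot enter the Cox model: {constant}")
    n_events = int(np.sum(np.asarray(events, dtype=int)))
    if n_events < covariates.shape[1]:
        raise ValueError(
            f"{n_events} events for {covariates.shape[1]} covariates: model unidentifiable"
        )
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame({
        "coef": summ["coef"],
        "se": summ["se(coef)"],
        "hr": summ["exp(coef)"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })
    out.index.name = "covariate"
    return out


# ---------------------------------------------------------------------------
# Risk definitions and the composite score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskRule:
    """One binary risk condition on a patient variable.

    ``op``: 'le' (value <= threshold is risky, boundary inclusive),
    'gt' (value > threshold is risky, boundary exclusive), or
    'eq' (categorical equality).
    """

    variable: str
    op: str
    threshold: object

    def applies(self, record: Mapping) -> bool:
        if self.variable not in record:
            raise KeyError(f"record lacks variable {self.variable!r}")
        v = record[self.variable]
        if self.op == "le":
            return bool(v <= self.threshold)
        if self.op == "gt":
            return bool(v > self.threshold)
        if self.op == "eq":
            return bool(v == self.threshold)
        raise ValueError(f"unknown op {self.op!r}")


@dataclass(frozen=True)
class RiskDefinition:
    """A named set of binary risk rules defining the composite score."""

    endpoint: str
    rules: tuple[RiskRule, ...]
    name: str = ""

    @property
    def max_score(self) -> int:
        return len(self.rules)


#: Overall-survival risk definition: smoking, low Ktrans, low Kep, low
#: PET uniformity (multivariate-selected factors and their cutoffs).
OS_RISK_DEFINITION = RiskDefinition(
    endpoint="os",
    name="multiparametric-os",
    rules=(
        RiskRule("smoking", "eq", True),
        RiskRule("ktrans", "le", 0.5512),
        RiskRule("kep", "le", 0.8872),
        RiskRule("uniformity", "le", 0.00381),
    ),
)

#: Recurrence-free-survival risk definition: hypopharyngeal subsite,
#: alcohol drinking, low Ktrans, low Kep.
RFS_RISK_DEFINITION = RiskDefinition(
    endpoint="rfs",
    name="multiparametric-rfs",
    rules=(
        RiskRule("subsite", "eq", "hypopharynx"),
        RiskRule("alcohol", "eq", True),
        RiskRule("ktrans", "le", 0.5512),
        RiskRule("kep", "le", 0.8872),
    ),
)

#: Prior two-factor system (conventional PET + DCE): low Kep, high SUV.
PREVIOUS_SYSTEM_DEFINITION = RiskDefinition(
    endpoint="os",
    name="conventional-pet-dce",
    rules=(
        RiskRule("kep", "le", 0.887),
        RiskRule("suv", "gt", 14.22),
    ),
)


def assign_score(record: Mapping, riskdef: RiskDefinition) -> int:
    """Composite score: number of satisfied risk rules (0..len(rules))."""
    return sum(rule.applies(record) for rule in riskdef.rules)


# ---------------------------------------------------------------------------
# Stratified comparison
# ---------------------------------------------------------------------------

def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ("os", "rfs"):
        raise ValueError("endpoint must be 'os' or 'rfs'")
    return f"{endpoint}_months", f"{endpoint}_event"


@dataclass
class ScoreResult:
    """Stratified outcome of a composite-score risk definition."""

    riskdef: RiskDefinition
    scores: pd.Series
    strata_counts: dict[int, int]
    km_curves: dict[int, KmCurve]
    logrank_statistic: float
    logrank_p: float
    reference_stratum: int
    hazard_ratios: pd.DataFrame | None
    caveat: str = SELECTION_BIAS_CAVEAT


def stratify_and_compare(
    cohort: pd.DataFrame,
    riskdef: RiskDefinition,
    endpoint: str | None = None,
) -> ScoreResult:
    """Score every patient, then compare the score strata.

    Produces per-stratum KM curves, the overall log-rank test across the
    occupied strata, and Cox hazard ratios of each stratum against the
    highest occupied score (worst prognosis group) as reference.  The HR
    table is omitted (None) when the Cox model is unidentifiable, e.g. a
    stratum without events.
    """
    tcol, ecol = _endpoint_columns(endpoint or riskdef.endpoint)
    scores = cohort.apply(lambda row: assign_score(row, riskdef), axis=1)
    occupied = sorted(scores.unique())
    if len(occupied) < 2:
        raise ValueError("only one occupied score stratum; nothing to compare")
    km_curves = {}
    groups = []
    for sc in occupied:
        sel = scores == sc
        km_curves[int(sc)] = km_estimate(cohort.loc[sel, tcol], cohort.loc[sel, ecol])
        groups.append((cohort.loc[sel, tcol].to_numpy(), cohort.loc[sel, ecol].to_numpy()))
    stat, p = logrank_test(groups)
    reference = int(max(occupied))
    dummies = pd.DataFrame({
        f"score_{int(sc)}": (scores == sc).astype(float)
        for sc in occupied if sc != reference
    })
    try:
        hr = fit_cox(dummies, cohort[tcol], cohort[ecol])
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"per-stratum Cox model unavailable: {exc}", stacklevel=2)
        hr = None
    return ScoreResult(
        riskdef=riskdef,
        scores=scores,
        strata_counts={int(sc): int((scores == sc).sum()) for sc in occupied},
        km_curves=km_curves,
        logrank_statistic=stat,
        logrank_p=p,
        reference_stratum=reference,
        hazard_ratios=hr,
    )


def compare_systems(
    cohort: pd.DataFrame,
    riskdef_a: RiskDefinition,
    riskdef_b: RiskDefinition,
    endpoint: str = "os",
) -> dict:
    """Side-by-side stratification report for two scoring systems.

    Returns a dict with one entry per system: stratum counts, overall
    log-rank statistic and p, and the per-stratum HR table (vs the worst
    stratum).  Strata with no patients are reported as n=0 without an HR.
    """
    report = {}
    for key, riskdef in (("system_a", riskdef_a), ("system_b", riskdef_b)):
        res = stratify_and_compare(cohort, riskdef, endpoint=endpoint)
        counts = {s: res.strata_counts.get(s, 0) for s in range(riskdef.max_score + 1)}
        report[key] = {
            "name": riskdef.name,
            "strata_n": counts,
            "logrank_statistic": res.logrank_statistic,
            "logrank_p": res.logrank_p,
            "reference_stratum": res.reference_stratum,
            "hazard_ratios": res.hazard_ratios,
        }
    report["caveat"] = SELECTION_BIAS_CAVEAT
    return report
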