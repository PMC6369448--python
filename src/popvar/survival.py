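"""Age-dependent penetrance from Kaplan-Meier survival curves.

Penetrance of a variant at age ``a`` is estimated as one minus the
product-limit (Kaplan-Meier) estimate of remaining disease-free at ``a``
among carriers.  Subjects enter at birth (no left truncation), so in a
healthy-volunteer population cohort the estimate is a *minimum*
penetrance: ascertainment removes severely affected individuals before
recruitment, and the true penetrance can only be higher.

Variance comes from Greenwood's formula; confidence intervals use the
log(-log) transform so they stay inside [0, 1] even for rare events.
Ties between events and censorings at the same age are resolved
events-first, the standard product-limit convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .exceptions import DataError

__all__ = [
    "SurvivalCurve",
    "PenetranceEstimate",
    "kaplan_meier",
    "penetrance_at_age",
    "compare_cohort_curves",
    "logrank_test",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood standard errors."""

    ages: np.ndarray  # distinct event ages, ascending
    survival: np.ndarray  # S(t) just after each event age
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray  # at risk just before each event age
    n_events: np.ndarray
    cohort_label: str = ""
    max_observed_age: float = float("inf")

    def survival_at(self, age: float) -> float:
        """S(age): the value at the last event age <= age (1 before any)."""
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def se_at(self, age: float) -> float:
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        return 0.0 if i < 0 else float(self.greenwood_se[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": self.cohort_label,
                "age": self.ages,
                "survival": self.survival,
                "se": self.greenwood_se,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass(frozen=True)
class PenetranceEstimate:
    age: float
    penetrance: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


def kaplan_meier(
    ages, events, cohort_label: str = "", entry_ages=None
) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``ages`` are event or censoring ages; ``events`` a boolean indicator
    (True = disease onset observed at that age, False = censored).
    ``entry_ages`` is accepted for API symmetry but must be zero/None:
    subjects enter at birth by design (minimum-penetrance convention).
    """
    t = np.asarray(ages, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DataError("empty survival input")
    if t.shape != e.shape:
        raise DataError("ages and event indicators must align")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise DataError("ages must be positive and finite")
    if entry_ages is not None and np.any(np.asarray(entry_ages) != 0):
        raise DataError("left truncation not supported: subjects enter at birth")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_ages = np.unique(t[e])
    n = t.size
    surv, ses, risks, events_at = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum
    for age in event_ages:
        # events-first tie rule: censorings at `age` are still at risk
        at_risk = int(np.sum(t >= age))
        d = int(np.sum((t == age) & e))
        s *= 1 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
            se = s * np.sqrt(gw)
        else:
            se = 0.0  # survival hit zero exactly
        surv.append(s)
        ses.append(se)
        risks.append(at_risk)
        events_at.append(d)
    return SurvivalCurve(
        ages=event_ages,
        survival=np.asarray(surv),
        greenwood_se=np.asarray(ses),
        n_at_risk=np.asarray(risks, dtype=int),
        n_events=np.asarray(events_at, dtype=int),
        cohort_label=cohort_label,
        max_observed_age=float(t.max()),
    )


def penetrance_at_age(
    curve: SurvivalCurve, age: float, alpha: float = 0.05
) -> PenetranceEstimate:
    """Penetrance 1 - S(age) with a log(-log) Greenwood interval.

    Ages beyond the last observed event carry the last survival value
    forward and are flagged as extrapolated.
    """
    s = curve.survival_at(age)
    se = curve.se_at(age)
    extrapolated = age > curve.max_observed_age
    if s <= 0.0 or s >= 1.0 or se == 0.0:
        lo, hi = 1 - s, 1 - s
    else:
        z = norm.ppf(1 - alpha / 2)
        theta = np.log(-np.log(s))
        se_theta = se / (s * abs(np.log(s)))
        s_lo = s ** np.exp(z * se_theta)   # lower survival bound
        s_hi = s ** np.exp(-z * se_theta)  # upper survival bound
        lo, hi = 1 - s_hi, 1 - s_lo
    return PenetranceEstimate(
        age=float(age),
        penetrance=1 - s,
        ci_low=float(lo),
        ci_high=float(hi),
        extrapolated=bool(extrapolated),
    )


def logrank_test(ages_1, events_1, ages_2, events_2) -> tuple[float, float]:
    """Two-sample log-rank test: (chi-square statistic, p-value)."""
    t1, e1 = np.asarray(ages_1, float), np.asarray(events_1, bool)
    t2, e2 = np.asarray(ages_2, float), np.asarray(events_2, bool)
    all_event_ages = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o_minus_e = 0.0
    var = 0.0
    for age in all_event_ages:
        n1 = int(np.sum(t1 >= age))
        n2 = int(np.sum(t2 >= age))
        d1 = int(np.sum((t1 == age) & e1))
        d2 = int(np.sum((t2 == age) & e2))
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        expected1 = d * n1 / n
        o_minus_e += d1 - expected1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def compare_cohort_curves(
    curves: list[SurvivalCurve],
    at_ages=None,
    clinical_label: str | None = None,
    population_label: str | None = None,
) -> pd.DataFrame:
    """Align several cohort survival curves on a common age grid.

    Returns one row per (age, cohort) with survival and penetrance, plus a
    ``penetrance_diff`` column (clinical minus population carriers) when
    the two labels are given.  Useful for contrasting clinically
    ascertained carriers with population-cohort carriers, where referral
    bias inflates apparent penetrance.
    """
    if len(curves) < 2:
        raise DataError("need at least two cohorts to compare")
    if at_ages is None:
        at_ages = np.unique(np.concatenate([c.ages for c in curves]))
    at_ages = np.asarray(at_ages, dtype=float)
    rows = []
    for c in curves:
        for a in at_ages:
            s = c.survival_at(a)
            rows.append(
                {
                    "cohort": c.cohort_label,
                    "age": a,
                    "survival": s,
                    "penetrance": 1 - s,
                }
            )
    table = pd.DataFrame(rows)
    if clinical_label is not None and population_label is not None:
        wide = table.pivot(index="age", columns="cohort", values="penetrance")
        diff = wide[clinical_label] - wide[population_label]
        table = table.merge(
            diff.rename("penetrance_diff").reset_index(), on="age", how="left"
        )
    return table
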