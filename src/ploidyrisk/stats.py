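"""Risk statistics: person-time rates, predictive values, association,
survival models and agreement.

Everything reported by the cohort analysis lives here:

* annual transformation rates per 100 person-years with log-normal CIs,
* PPV / NPV / sensitivity / specificity from 2x2 tables with *unclipped*
  Wald intervals (bounds may leave [0, 100]%, as is conventional when the
  point estimate sits near a boundary),
* AND/OR combinations of the ploidy and dysplasia tests,
* the Pearson chi-square association between ploidy and grade,
* Kaplan-Meier estimates, log-rank tests and age/sex-adjusted Cox
  proportional-hazards models (via lifelines, Efron ties),
* Cohen's kappa for inter-method diagnostic agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GRADES

__all__ = [
    "RateEstimate",
    "PredictiveValue",
    "HazardEstimate",
    "annual_rate",
    "proportion_wald_ci",
    "predictive_values",
    "predictive_values_from_counts",
    "combine_tests",
    "chi_square_association",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cohen_kappa",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RateEstimate:
    """Events per 100 person-years with a 95% CI.

    With zero events the rate is 0 and the CI is reported as None (the
    log-normal interval is undefined at zero).
    """

    stratum: str
    events: int
    person_years: float
    annual_rate_pct: float
    ci95: tuple[float, float] | None


@dataclass(frozen=True)
class PredictiveValue:
    """2x2 diagnostic-test summary with unclipped Wald 95% CIs (percent)."""

    test_label: str
    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None


@dataclass(frozen=True)
class HazardEstimate:
    """One Cox model term: hazard ratio, 95% CI, p-value."""

    term: str
    hr: float
    ci95: tuple[float, float]
    p_value: float
    adjustment: str
    n: int
    n_events: int


def annual_rate(events: int, person_years: float, stratum: str = "") -> RateEstimate:
    """Annual transformation rate, percent per person-year.

    ``rate = 100 * events / person_years``; for ``events >= 1`` the 95% CI
    is the log-normal interval ``rate * exp(±1.96 / sqrt(events))``, the
    standard person-time construction.  Zero events give rate 0 with a null
    CI (the convention used when a stratum has no transformations).
    """
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise ValueError(f"events must be >= 0, got {events}")
    rate = 100.0 * events / person_years
    if events == 0:
        return RateEstimate(stratum, 0, person_years, 0.0, None)
    half = np.exp(Z95 / np.sqrt(events))
    return RateEstimate(stratum, int(events), person_years, rate,
                        (rate / half, rate * half))


def proportion_wald_ci(k: int, n: int) -> tuple[float, float]:
    """Unclipped Wald 95% CI for a binomial proportion, in percent.

    ``p ± 1.96 * sqrt(p (1 - p) / n)``.  Bounds are not clipped to
    [0, 100]% — near-degenerate proportions legitimately print bounds such
    as 100.8%.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    p = k / n
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return (100.0 * (p - half), 100.0 * (p + half))


def predictive_values_from_counts(tp: int, fp: int, fn: int, tn: int,
                                  test_label: str = "") -> PredictiveValue:
    """Predictive values from a 2x2 table with transformation as reference.

    Undefined measures (empty margin) are returned as None rather than NaN,
    with the counts preserved.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    def measure(k: int, n: int) -> tuple[float | None, tuple[float, float] | None]:
        if n == 0:
            return None, None
        return 100.0 * k / n, proportion_wald_ci(k, n)

    ppv, ppv_ci = measure(tp, tp + fp)
    npv, npv_ci = measure(tn, tn + fn)
    sens, sens_ci = measure(tp, tp + fn)
    spec, spec_ci = measure(tn, tn + fp)
    return PredictiveValue(test_label, tp, fp, fn, tn, ppv, npv, sens, spec,
                           ppv_ci, npv_ci, sens_ci, spec_ci)


def predictive_values(rows: pd.DataFrame,
                      positive_test: Callable[[pd.DataFrame], pd.Series],
                      test_label: str = "") -> PredictiveValue:
    """Build the 2x2 from an analysis table and a test predicate.

    ``rows`` needs a boolean ``event`` column; ``positive_test`` maps the
    frame to a boolean Series marking test-positive patients.
    """
    pos = np.asarray(positive_test(rows), dtype=bool)
    ev = np.asarray(rows["event"], dtype=bool)
    tp = int(np.sum(pos & ev))
    fp = int(np.sum(pos & ~ev))
    fn = int(np.sum(~pos & ev))
    tn = int(np.sum(~pos & ~ev))
    return predictive_values_from_counts(tp, fp, fn, tn, test_label)


def combine_tests(rows: pd.DataFrame,
                  ploidy_set: Sequence[str],
                  operator: Literal["AND", "OR"],
                  grade_set: Sequence[str],
                  indicator: Literal["positive", "negative"] = "positive",
                  test_label: str = "") -> PredictiveValue:
    """Predictive values of a combined ploidy/grade test.

    The indicator is ``(ploidy in ploidy_set) OP (grade in grade_set)``.
    For abnormal combinations (e.g. aneuploid AND severe) the indicator
    marks test-*positive* patients and PPV is the quantity of interest; for
    benign combinations (e.g. diploid-or-tetraploid AND non-dysplastic) it
    marks test-*negative* patients and NPV is of interest.  Both readings
    produce the full 2x2.
    """
    if not ploidy_set or not grade_set:
        raise ValueError("ploidy_set and grade_set must be non-empty")
    if operator not in ("AND", "OR"):
        raise ValueError(f"operator must be AND or OR, got {operator!r}")
    in_p = rows["index_ploidy"].isin(list(ploidy_set))
    in_g = rows["index_grade"].isin(list(grade_set))
    ind = (in_p & in_g) if operator == "AND" else (in_p | in_g)
    positive = ind if indicator == "positive" else ~ind
    return predictive_values(rows, lambda _: positive, test_label)


def chi_square_association(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(statistic, df, p)`` with ``df = (r - 1)(c - 1)``.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def km_estimate(rows: pd.DataFrame, strata: str | None = None,
                at_risk_times: Sequence[float] | None = None
                ) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates, optionally per stratum.

    Returns a mapping ``stratum -> DataFrame(time, survival, at_risk)``; the
    key for an unstratified fit is ``"all"``.  When ``at_risk_times`` is
    given, an ``at_risk`` table row is appended per requested time (the
    number-at-risk annotations shown under survival plots).
    """
    from lifelines import KaplanMeierFitter

    out: dict[str, pd.DataFrame] = {}
    groups = [("all", rows)] if strata is None else list(rows.groupby(strata))
    for name, grp in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time_years"], grp["event"].astype(bool))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        ev_table = kmf.event_table
        sf["at_risk"] = ev_table["at_risk"].reindex(
            kmf.survival_function_.index).to_numpy()
        if at_risk_times is not None:
            extra = pd.DataFrame({
                "time": list(at_risk_times),
                "survival": [float(kmf.predict(t)) for t in at_risk_times],
                "at_risk": [int((grp["time_years"] >= t).sum()) for t in at_risk_times],
            })
            sf = (pd.concat([sf, extra], ignore_index=True)
                  .sort_values("time").reset_index(drop=True))
        out[str(name)] = sf
    return out


def logrank_test(rows: pd.DataFrame, strata: str) -> tuple[float, int, float]:
    """Log-rank comparison of survival across the strata of a column.

    ``df = number of strata - 1``; strata with zero events are permitted and
    contribute their at-risk time.
    """
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(rows["time_years"], rows[strata],
                                    rows["event"].astype(bool))
    n_groups = rows[strata].nunique()
    return float(res.test_statistic), int(n_groups - 1), float(res.p_value)


def _encode_design(rows: pd.DataFrame, exposures: Sequence[str]
                   ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Dummy-code exposures (reference: none-grade / diploid) plus age, sex.

    Constant covariates are dropped with a warning.  Returns
    ``(design, term_columns, dropped)``.
    """
    design = pd.DataFrame({
        "time_years": rows["time_years"].astype(float),
        "event": rows["event"].astype(bool),
    }, index=rows.index)
    terms: list[str] = []
    for expo in exposures:
        col = "index_grade" if expo == "dysplasia" else "index_ploidy"
        levels = [g for g in (GRADES if expo == "dysplasia"
                              else ("diploid", "aneuploid"))
                  if g in set(rows[col])]
        for lev in levels[1:]:  # first present level is the reference
            name = f"{expo}_{lev}"
            design[name] = (rows[col] == lev).astype(float)
            terms.append(name)
    design["age"] = rows["age_at_index"].astype(float)
    design["sex_male"] = (rows["sex"] == "male").astype(float)

    dropped = [c for c in design.columns
               if c not in ("time_years", "event") and design[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", stacklevel=3)
        design = design.drop(columns=dropped)
        terms = [t for t in terms if t not in dropped]
    return design, terms, dropped


def cox_fit(rows: pd.DataFrame,
            exposure: Literal["dysplasia", "ploidy"],
            adjustment: Literal["age_sex", "age_sex_mutual"] = "age_sex"
            ) -> list[HazardEstimate]:
    """Cox proportional-hazards fit for one exposure.

    ``age_sex`` fits exposure + age + sex; ``age_sex_mutual`` additionally
    adjusts grade and ploidy for each other.  Reference levels are
    none-grade and diploid; tetraploid patients are dropped from any model
    containing a ploidy term (too few for a stable contrast, merged with
    diploid only for predictive values).  Ties are handled by the Efron
    approximation; age is continuous, sex binary.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    exposures = [exposure] if adjustment == "age_sex" else ["dysplasia", "ploidy"]
    data = rows
    if "ploidy" in exposures:
        data = rows[rows["index_ploidy"].isin(["diploid", "aneuploid"])]
    design, terms, _ = _encode_design(data, exposures)
    if design["event"].sum() == 0:
        raise ValueError("no events: Cox model cannot be fitted")

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time_years", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"degenerate Cox fit (separation or no-event stratum): "
                         f"{exc}") from exc
    summ = cph.summary
    out: list[HazardEstimate] = []
    for term in terms:
        row = summ.loc[term]
        out.append(HazardEstimate(
            term, float(np.exp(row["coef"])),
            (float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
            float(row["p"]), adjustment, int(len(design)),
            int(design["event"].sum())))
    return out


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa, ``(po - pe) / (1 - pe)``; 1.0 for identical vectors."""
    from sklearn.metrics import cohen_kappa_score

    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if a == b:
        return 1.0  # sklearn returns nan when a single class is present
    return float(cohen_kappa_score(a, b))
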