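"""Cohort-level risk model: one object from patients to every reported
statistic.

``TransformationRiskModel`` wraps the whole analysis stage the way a
statsmodels model wraps a fit: construct it from a cohort (or an already
built analysis table), call :meth:`~TransformationRiskModel.fit`, and read
the results object — per-stratum annual transformation rates, predictive
values of single and combined tests, the ploidy–grade association,
Kaplan-Meier / log-rank comparisons and age/sex-adjusted Cox hazard
ratios — or print ``results.summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GRADES, PatientRecord
from .pipeline import apply_exclusions, build_analysis_table, subgroup_split
from .stats import (HazardEstimate, PredictiveValue, annual_rate,
                    chi_square_association, combine_tests, cox_fit, km_estimate,
                    logrank_test, predictive_values)

__all__ = ["TransformationRiskModel", "TransformationRiskResults"]

_STRATA = {"dysplasia": list(GRADES),
           "ploidy": ["diploid", "tetraploid", "aneuploid"]}
_STRATUM_COL = {"dysplasia": "index_grade", "ploidy": "index_ploidy"}

# Table-6-style combination rows: (ploidy set, operator, grade set, indicator)
_COMBINATIONS = [
    (("diploid", "tetraploid"), "AND", ("none",), "negative"),
    (("diploid", "tetraploid"), "AND", ("none", "mild"), "negative"),
    (("diploid", "tetraploid"), "AND", GRADES, "negative"),
    (("diploid", "tetraploid"), "OR", ("none",), "negative"),
    (("aneuploid",), "AND", ("severe",), "positive"),
    (("aneuploid",), "AND", ("severe", "moderate"), "positive"),
    (("aneuploid",), "OR", ("severe",), "positive"),
    (("aneuploid",), "OR", ("severe", "moderate"), "positive"),
]


@dataclass
class TransformationRiskResults:
    """Everything the fitted model reports.

    Attributes ending in ``_`` follow the scikit-learn convention of being
    set by the fit.  ``rates_`` is a tidy frame (axis, subgroup, stratum,
    n, events, person_years, annual_rate_pct, ci_lo, ci_hi);
    ``predictive_values_`` and ``hazards_`` are lists of result dataclasses;
    ``chi_square_`` is ``(statistic, df, p)`` on the diploid+tetraploid
    collapsed ploidy x grade table (``chi_square_full_`` keeps the
    uncollapsed 3x4 version); ``logrank_`` maps (axis, subgroup) to
    ``(statistic, df, p)``.
    """

    tables_: dict = field(default_factory=dict)
    exclusions_: pd.DataFrame | None = None
    rates_: pd.DataFrame | None = None
    predictive_values_: list[PredictiveValue] = field(default_factory=list)
    combinations_: list[PredictiveValue] = field(default_factory=list)
    chi_square_: tuple[float, int, float] | None = None
    chi_square_full_: tuple[float, int, float] | None = None
    km_: dict = field(default_factory=dict)
    logrank_: dict = field(default_factory=dict)
    hazards_: list[HazardEstimate] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Malignant-transformation risk analysis", "=" * 40]
        if self.chi_square_ is not None:
            s, d, p = self.chi_square_
            lines.append(f"Ploidy-grade association (collapsed): "
                         f"chi2={s:.1f}, df={d}, p={p:.2g}")
        if self.rates_ is not None and len(self.rates_):
            lines.append("")
            lines.append("Annual transformation rates (% per person-year):")
            for _, r in self.rates_.iterrows():
                ci = ("" if np.isnan(r["ci_lo"]) else
                      f" ({r['ci_lo']:.2f}, {r['ci_hi']:.2f})")
                lines.append(
                    f"  {r['axis']:<9} {r['subgroup']:<9} {r['stratum']:<10} "
                    f"n={int(r['n']):>4} events={int(r['events']):>3} "
                    f"py={r['person_years']:8.2f} rate={r['annual_rate_pct']:.2f}%{ci}")
        if self.predictive_values_:
            lines.append("")
            lines.append("Predictive values (%):")
            for pv in self.predictive_values_ + self.combinations_:
                if pv.ppv is not None:
                    lines.append(f"  {pv.test_label:<40} PPV={pv.ppv:5.1f} "
                                 f"({pv.ppv_ci[0]:.1f}, {pv.ppv_ci[1]:.1f})")
                if pv.npv is not None:
                    lines.append(f"  {pv.test_label:<40} NPV={pv.npv:5.1f} "
                                 f"({pv.npv_ci[0]:.1f}, {pv.npv_ci[1]:.1f})")
        for (axis, sub), (s, d, p) in self.logrank_.items():
            lines.append(f"Log-rank [{axis}, {sub}]: chi2={s:.2f}, df={d}, p={p:.2g}")
        for hz in self.hazards_:
            lines.append(f"Cox [{hz.adjustment}] {hz.term}: HR={hz.hr:.2f} "
                         f"({hz.ci95[0]:.2f}, {hz.ci95[1]:.2f}) p={hz.p_value:.3g}")
        for w in self.warnings_:
            lines.append(f"NOTE: {w}")
        return "\n".join(lines)

    def plot_km(self, axis: str = "dysplasia", subgroup: str = "including",
                ax=None):
        """Step plot of the progression-free proportion per stratum.

        Requires the survival stage to have been fitted; returns the
        matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if (axis, subgroup) not in self.km_:
            raise ValueError(f"no Kaplan-Meier fit for ({axis}, {subgroup})")
        if ax is None:
            _, ax = plt.subplots()
        for stratum, sf in self.km_[(axis, subgroup)].items():
            ax.step(sf["time"], sf["survival"], where="post", label=stratum)
        ax.set_xlabel("years since index lesion")
        ax.set_ylabel("progression-free proportion")
        ax.set_ylim(0, 1.05)
        ax.legend(title=axis)
        ax.set_title(f"{axis} ({subgroup} <6-month transformations)")
        return ax


class TransformationRiskModel:
    """Malignant-transformation risk analysis of a biopsy cohort.

    Parameters
    ----------
    patients : sequence of PatientRecord
        The cohort; index selection, endpoints, subgroups and exclusions
        are derived internally.
    fit_survival : bool
        Whether to attempt KM / log-rank / Cox (needs enough events; small
        synthetic cohorts may only support the counting statistics).
    """

    def __init__(self, patients: Sequence[PatientRecord],
                 fit_survival: bool = True) -> None:
        self.patients = list(patients)
        self.fit_survival = fit_survival

    @classmethod
    def from_cohort(cls, patients: Sequence[PatientRecord], **kwargs
                    ) -> "TransformationRiskModel":
        return cls(patients, **kwargs)

    def fit(self) -> TransformationRiskResults:
        res = TransformationRiskResults()
        retained, ledger = apply_exclusions(self.patients)
        res.exclusions_ = ledger

        # analysis tables per axis and subgroup
        for axis in ("dysplasia", "ploidy"):
            table = build_analysis_table(retained[axis], axis)
            incl, excl = subgroup_split(table)
            res.tables_[(axis, "including")] = incl
            res.tables_[(axis, "excluding")] = excl

        # person-time rates
        rate_rows = []
        for (axis, sub), tbl in res.tables_.items():
            col = _STRATUM_COL[axis]
            strata = _STRATA[axis] + ["all"]
            for stratum in strata:
                part = tbl if stratum == "all" else tbl[tbl[col] == stratum]
                py = float(part["time_years"].sum())
                if py <= 0:
                    continue
                est = annual_rate(int(part["event"].sum()), py, stratum)
                rate_rows.append({
                    "axis": axis, "subgroup": sub, "stratum": stratum,
                    "n": len(part), "events": est.events,
                    "person_years": est.person_years,
                    "annual_rate_pct": est.annual_rate_pct,
                    "ci_lo": est.ci95[0] if est.ci95 else np.nan,
                    "ci_hi": est.ci95[1] if est.ci95 else np.nan})
        res.rates_ = pd.DataFrame(rate_rows)

        # predictive values on the full (ploidy-axis) cohort, per subgroup
        for sub in ("including", "excluding"):
            tbl = res.tables_[("ploidy", sub)]
            if not len(tbl):
                continue
            for grade in GRADES:
                res.predictive_values_.append(predictive_values(
                    tbl, lambda t, g=grade: t["index_grade"] == g,
                    f"grade={grade} [{sub}]"))
            res.predictive_values_.append(predictive_values(
                tbl, lambda t: t["index_ploidy"].isin(["diploid", "tetraploid"]),
                f"dip-or-tet [{sub}]"))
            res.predictive_values_.append(predictive_values(
                tbl, lambda t: t["index_ploidy"] == "aneuploid",
                f"aneuploid [{sub}]"))
            for pset, op, gset, ind in _COMBINATIONS:
                label = f"{'/'.join(pset)} {op} {'/'.join(gset)} [{sub}]"
                res.combinations_.append(combine_tests(
                    tbl, pset, op, gset, indicator=ind, test_label=label))

        # ploidy-grade association on the full cohort cross-table
        full = res.tables_[("ploidy", "including")]
        if len(full):
            ct = pd.crosstab(full["index_ploidy"], full["index_grade"])
            ct = ct.reindex(index=["diploid", "tetraploid", "aneuploid"],
                            columns=list(GRADES), fill_value=0)
            collapsed = np.vstack([ct.loc["diploid"] + ct.loc["tetraploid"],
                                   ct.loc["aneuploid"]])
            keep = collapsed.sum(axis=0) > 0
            try:
                res.chi_square_ = chi_square_association(collapsed[:, keep])
                res.chi_square_full_ = chi_square_association(
                    ct.to_numpy()[ct.to_numpy().sum(axis=1) > 0][:, keep])
            except ValueError as exc:
                res.warnings_.append(f"chi-square unavailable: {exc}")

        if self.fit_survival:
            self._fit_survival(res)
        return res

    def _fit_survival(self, res: TransformationRiskResults) -> None:
        for (axis, sub), tbl in res.tables_.items():
            if not len(tbl) or tbl["event"].sum() == 0:
                res.warnings_.append(f"no events on ({axis}, {sub}); "
                                     "survival stage skipped")
                continue
            col = _STRATUM_COL[axis]
            res.km_[(axis, sub)] = km_estimate(tbl, strata=col)
            if tbl[col].nunique() > 1:
                res.logrank_[(axis, sub)] = logrank_test(tbl, col)
            # the mutually adjusted model contains both exposures; fitting it
            # once per subgroup (on the dysplasia-axis table, which honours
            # the synchronous-worst exclusion) avoids duplicate estimates
            adjustments = ("age_sex",) if axis == "ploidy" else (
                "age_sex", "age_sex_mutual")
            for adj in adjustments:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fitted = cox_fit(tbl, axis, adj)
                    res.hazards_.extend(
                        replace(hz, term=f"[{axis},{sub}] {hz.term}")
                        for hz in fitted)
                except Exception as exc:  # degenerate fits are reported, not fatal
                    res.warnings_.append(
                        f"Cox fit failed ({axis}, {sub}, {adj}): {exc}")
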