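"""From dated biopsies and outcomes to the per-patient analysis table.

Implements the bookkeeping conventions of the cohort analysis:

* **first-worst index selection** — per analysis axis (dysplasia grade or
  ploidy), the index lesion is the earliest biopsy attaining the patient's
  most abnormal result; if every result is normal, the earliest biopsy;
* **four-outcome endpoint** — the endpoint date is the earliest of
  carcinoma diagnosis (event), death from oral carcinoma (event), death from
  any other cause (censoring) and last follow-up (censoring);
* **6-month subgrouping** — analyses are run both including and excluding
  patients whose carcinoma developed less than 6 months after the index
  lesion (early transformation is read as a carcinoma missed at biopsy);
* **synchronous-worst exclusion** — a patient whose worst dysplasia grade
  was diagnosed simultaneously with the carcinoma is excluded from the
  dysplasia-axis survival analysis but kept on the ploidy axis when a prior
  ploidy result exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Literal, Sequence

import pandas as pd

from .cohort import DAYS_PER_YEAR, GRADES, PLOIDY_LABELS, BiopsyRecord, PatientRecord
from .exceptions import DataError

__all__ = [
    "AnalysisRow",
    "select_index_lesion",
    "define_endpoint",
    "build_analysis_table",
    "subgroup_split",
    "apply_exclusions",
]

Axis = Literal["dysplasia", "ploidy"]

_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}
_PLOIDY_RANK = {p: i for i, p in enumerate(PLOIDY_LABELS)}  # diploid < tetra < aneu

EARLY_TRANSFORM_YEARS = 0.5  # "within 6 months" cut, strict


@dataclass(frozen=True)
class AnalysisRow:
    """One patient's contribution to a survival/rate analysis."""

    patient_id: str
    index_date: date
    index_grade: str
    index_ploidy: str
    age_at_index: float
    sex: str
    time_years: float
    event: bool


def _severity(biopsy: BiopsyRecord, axis: Axis) -> int | None:
    """Rank of a biopsy on the axis; None when the result is not valid
    (inadequate ploidy)."""
    if axis == "dysplasia":
        return _GRADE_RANK[biopsy.grade]
    return _PLOIDY_RANK.get(biopsy.ploidy)  # inadequate -> None


def select_index_lesion(patient: PatientRecord, axis: Axis) -> BiopsyRecord:
    """Earliest biopsy attaining the patient's most abnormal result.

    Severity orders: none < mild < moderate < severe;
    diploid < tetraploid < aneuploid.  When every result is normal the
    earliest biopsy is returned (the rule reduces to it).  Same-date ties at
    equal severity break stably by biopsy identifier.
    """
    valid = [b for b in patient.biopsies if _severity(b, axis) is not None]
    if not valid:
        raise DataError(
            f"patient {patient.patient_id}: no valid result on the {axis} axis")
    worst = max(_severity(b, axis) for b in valid)
    candidates = [b for b in valid if _severity(b, axis) == worst]
    return min(candidates, key=lambda b: (b.date, b.biopsy_id))


def define_endpoint(patient: PatientRecord, index_date: date | None = None
                    ) -> tuple[float, bool]:
    """Time in years from index to the earliest of the four outcomes.

    Events: carcinoma diagnosis; death from oral carcinoma (when no earlier
    diagnosis date exists, the death date stands in for the transformation
    date).  Censorings: death from any other cause; last follow-up.
    """
    if index_date is None:
        index_date = min(b.date for b in patient.biopsies)
    candidates: list[tuple[date, bool]] = []
    if patient.transformation_date is not None:
        candidates.append((patient.transformation_date, True))
    if patient.death_date is not None:
        is_event = patient.death_cause == "oral_carcinoma"
        candidates.append((patient.death_date, is_event))
    candidates.append((patient.last_followup_date, False))
    endpoint, event = min(candidates, key=lambda t: (t[0], not t[1]))
    days = (endpoint - index_date).days
    if days < 0:
        raise DataError(
            f"patient {patient.patient_id}: endpoint {endpoint} precedes "
            f"index date {index_date}")
    return days / DAYS_PER_YEAR, event


def build_analysis_table(patients: Sequence[PatientRecord], axis: Axis
                         ) -> pd.DataFrame:
    """Analysis table for one axis: one row per patient.

    Columns: patient_id, index_date, index_grade, index_ploidy,
    age_at_index, sex, time_years, event.  Patients with no valid result on
    the axis are silently dropped (they appear in the exclusion ledger of
    :func:`apply_exclusions`).
    """
    rows: list[AnalysisRow] = []
    for p in patients:
        try:
            idx = select_index_lesion(p, axis)
        except DataError:
            continue
        t, ev = define_endpoint(p, idx.date)
        rows.append(AnalysisRow(p.patient_id, idx.date, idx.grade, idx.ploidy,
                                p.age_at_index, p.sex, t, ev))
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["patient_id", "index_date", "index_grade",
                                 "index_ploidy", "age_at_index", "sex",
                                 "time_years", "event"])


def subgroup_split(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(all patients, patients excluding transformation within 6 months).

    The second frame removes patients with an *event* before 0.5 years;
    censored patients are never removed.
    """
    early = rows["event"].astype(bool) & (rows["time_years"] < EARLY_TRANSFORM_YEARS)
    return rows.copy(), rows.loc[~early].copy()


def apply_exclusions(patients: Sequence[PatientRecord]
                     ) -> tuple[dict[str, list[PatientRecord]], pd.DataFrame]:
    """Per-axis survival-analysis exclusions with a ledger.

    A patient whose first-worst dysplasia biopsy is dated the same day as
    the carcinoma is excluded from the dysplasia axis (the grade carries no
    predictive lead time); they stay on the ploidy axis when a valid prior
    ploidy result exists.  Patients with no valid result on an axis are
    excluded from that axis.

    Returns ``(retained, ledger)`` where ``retained`` maps axis name to the
    patient list and ``ledger`` has one row per (patient, axis) exclusion
    with a reason.
    """
    retained: dict[str, list[PatientRecord]] = {"dysplasia": [], "ploidy": []}
    ledger_rows: list[dict] = []
    for p in patients:
        for axis in ("dysplasia", "ploidy"):
            try:
                idx = select_index_lesion(p, axis)
            except DataError:
                ledger_rows.append({"patient_id": p.patient_id, "axis": axis,
                                    "reason": "no_valid_result"})
                continue
            if (axis == "dysplasia" and p.transformation_date is not None
                    and idx.date == p.transformation_date):
                ledger_rows.append({"patient_id": p.patient_id, "axis": axis,
                                    "reason": "synchronous_worst_grade"})
                continue
            retained[axis].append(p)
    ledger = pd.DataFrame(ledger_rows, columns=["patient_id", "axis", "reason"])
    return retained, ledger
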