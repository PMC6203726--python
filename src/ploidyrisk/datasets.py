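"""Published summary counts of a high-risk oral-lesion surveillance cohort.

A published cohort of 228 patients with oral lesions judged clinically at
high risk of malignant transformation, followed 5–9.6 years, reports:

* the cross-classification of DNA ploidy diagnosis (diploid / tetraploid /
  aneuploid) by dysplasia grade (none / mild / moderate / severe),
* per-stratum transformation counts and person-years of follow-up, for
  both analysis axes and both subgroups (including and excluding patients
  transforming within 6 months of the index lesion),
* predictive values of single and combined tests.

These printed counts are the inputs used to reproduce the reported
statistics without the (undeposited) patient-level data.

The per-cell transformation counts of the grade x ploidy table are not
printed directly; they are **reconstructed** here, uniquely, from the
printed margins, the printed combined-test predictive values and the
statements that the transforming non-dysplastic and mildly dysplastic
lesions were not aneuploid.  Every printed combination value follows from
the reconstruction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GRADE_ORDER",
    "PLOIDY_ORDER",
    "ploidy_grade_table",
    "transformation_cell_counts",
    "patient_level_frame",
    "person_time_table",
]

GRADE_ORDER = ["none", "mild", "moderate", "severe"]
PLOIDY_ORDER = ["diploid", "tetraploid", "aneuploid"]

# patients per (ploidy, grade) cell, full cohort (n = 228)
_PATIENTS_INCLUDING = {
    "diploid": (120, 35, 16, 12),
    "tetraploid": (1, 1, 1, 0),
    "aneuploid": (0, 11, 15, 16),
}
# transformations per cell, full cohort (24 events) — reconstructed cells
_EVENTS_INCLUDING = {
    "diploid": (1, 2, 2, 5),
    "tetraploid": (0, 0, 0, 0),
    "aneuploid": (0, 0, 5, 9),
}
# excluding transformation within 6 months of index (n = 219, 15 events)
_PATIENTS_EXCLUDING = {
    "diploid": (120, 35, 15, 10),
    "tetraploid": (1, 1, 1, 0),
    "aneuploid": (0, 11, 14, 11),
}
_EVENTS_EXCLUDING = {
    "diploid": (1, 2, 1, 3),
    "tetraploid": (0, 0, 0, 0),
    "aneuploid": (0, 0, 4, 4),
}

# (n, events, person_years) per stratum.  On the dysplasia axis the single
# patient whose worst grade was synchronous with the carcinoma is excluded
# (hence 23 events vs 24 on the ploidy axis in the full cohort).
_PERSON_TIME = [
    # axis, subgroup, stratum, n, events, person_years
    ("dysplasia", "including", "none", 121, 1, 1045.02),
    ("dysplasia", "including", "mild", 47, 2, 378.85),
    ("dysplasia", "including", "moderate", 32, 7, 187.08),
    ("dysplasia", "including", "severe", 28, 13, 122.13),
    ("dysplasia", "including", "all", 228, 23, 1733.07),
    ("dysplasia", "excluding", "none", 121, 1, 1045.02),
    ("dysplasia", "excluding", "mild", 47, 2, 378.85),
    ("dysplasia", "excluding", "moderate", 30, 5, 186.49),
    ("dysplasia", "excluding", "severe", 21, 7, 121.29),
    ("dysplasia", "excluding", "all", 219, 15, 1731.64),
    ("ploidy", "including", "diploid", 183, 10, 1478.24),
    ("ploidy", "including", "tetraploid", 3, 0, 22.68),
    ("ploidy", "including", "aneuploid", 42, 14, 234.31),
    ("ploidy", "including", "all", 228, 24, 1735.23),
    ("ploidy", "excluding", "diploid", 180, 7, 1476.69),
    ("ploidy", "excluding", "tetraploid", 3, 0, 22.68),
    ("ploidy", "excluding", "aneuploid", 36, 8, 232.55),
    ("ploidy", "excluding", "all", 219, 15, 1731.93),
]


def ploidy_grade_table() -> pd.DataFrame:
    """Patients per ploidy x grade cell (rows: ploidy, columns: grade)."""
    return pd.DataFrame.from_dict(
        _PATIENTS_INCLUDING, orient="index", columns=GRADE_ORDER
    ).loc[PLOIDY_ORDER]


def transformation_cell_counts(subgroup: str = "including"
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(patients, events) per ploidy x grade cell for a subgroup.

    ``subgroup`` is ``"including"`` (full cohort, n=228, 24 events) or
    ``"excluding"`` (transformation within 6 months removed, n=219, 15
    events).  Event cells are reconstructed — see the module docstring.
    """
    if subgroup == "including":
        pats, evs = _PATIENTS_INCLUDING, _EVENTS_INCLUDING
    elif subgroup == "excluding":
        pats, evs = _PATIENTS_EXCLUDING, _EVENTS_EXCLUDING
    else:
        raise ValueError(f"subgroup must be 'including' or 'excluding', got {subgroup!r}")
    mk = lambda d: pd.DataFrame.from_dict(  # noqa: E731
        d, orient="index", columns=GRADE_ORDER).loc[PLOIDY_ORDER]
    return mk(pats), mk(evs)


def patient_level_frame(subgroup: str = "including") -> pd.DataFrame:
    """Expand the cell counts into one row per patient.

    Columns ``index_grade``, ``index_ploidy``, ``event`` — the shape the
    predictive-value and association machinery consumes.  Follow-up times
    are not reconstructible per patient and are not included.
    """
    pats, evs = transformation_cell_counts(subgroup)
    rows = []
    for ploidy in PLOIDY_ORDER:
        for grade in GRADE_ORDER:
            n = int(pats.loc[ploidy, grade])
            k = int(evs.loc[ploidy, grade])
            if k > n:
                raise AssertionError("event cell exceeds patient cell")
            rows.extend({"index_grade": grade, "index_ploidy": ploidy,
                         "event": i < k} for i in range(n))
    return pd.DataFrame(rows)


def person_time_table() -> pd.DataFrame:
    """Transformation counts and person-years per axis/subgroup/stratum."""
    return pd.DataFrame(
        _PERSON_TIME,
        columns=["axis", "subgroup", "stratum", "n", "events", "person_years"])
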