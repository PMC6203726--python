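"""Synthetic patient cohorts with dated biopsies and malignant outcomes.

Emulates the joint structure of a surveillance cohort of patients with
clinically high-risk oral lesions: a dysplasia-grade distribution, a ploidy
distribution conditional on grade, stratum-specific constant transformation
hazards (exponential event times), administrative censoring over a 5–9.6
year follow-up window, competing death from other causes, and repeat
biopsies so the first-worst index-selection logic is exercised.

Defaults reproduce the marginals of a published 228-patient cohort:
grade counts 121/47/32/28 (none/mild/moderate/severe), a row-stochastic
ploidy-given-grade matrix in which no non-dysplastic lesion is aneuploid,
and grade-specific annual transformation rates of 0.09/0.53/3.74/10.64% per
person-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError

__all__ = [
    "GRADES",
    "PLOIDY_LABELS",
    "BiopsyRecord",
    "PatientRecord",
    "CohortSimConfig",
    "simulate_cohort",
    "export_cohort",
    "import_cohort",
]

GRADES = ("none", "mild", "moderate", "severe")
PLOIDY_LABELS = ("diploid", "tetraploid", "aneuploid")
DAYS_PER_YEAR = 365.25

#: ploidy | grade, rows = grade, cols = (diploid, tetraploid, aneuploid)
DEFAULT_PLOIDY_GIVEN_GRADE = {
    "none": (120 / 121, 1 / 121, 0.0),
    "mild": (35 / 47, 1 / 47, 11 / 47),
    "moderate": (16 / 32, 1 / 32, 15 / 32),
    "severe": (12 / 28, 0.0, 16 / 28),
}

#: grade-specific transformation hazards, events per person-year
DEFAULT_ANNUAL_HAZARD = {
    "none": 0.0009,
    "mild": 0.0053,
    "moderate": 0.0374,
    "severe": 0.1064,
}


@dataclass(frozen=True)
class BiopsyRecord:
    """One dated biopsy with its histology grade and ploidy diagnosis."""

    patient_id: str
    biopsy_id: str
    date: date
    grade: str
    ploidy: str

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ConfigError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.ploidy not in PLOIDY_LABELS + ("inadequate",):
            raise ConfigError(f"unknown ploidy label {self.ploidy!r}")


@dataclass
class PatientRecord:
    """A patient: date-ordered biopsy series plus outcome dates.

    The unit of analysis for malignant transformation is the patient.
    """

    patient_id: str
    age_at_index: float
    sex: str
    biopsies: list[BiopsyRecord]
    last_followup_date: date
    transformation_date: date | None = None
    death_date: date | None = None
    death_cause: str = "none"  # none | oral_carcinoma | other

    def __post_init__(self) -> None:
        if not self.biopsies:
            raise ConfigError(f"patient {self.patient_id} has no biopsies")
        self.biopsies = sorted(self.biopsies, key=lambda b: (b.date, b.biopsy_id))


@dataclass
class CohortSimConfig:
    """Cohort generator configuration.

    ``annual_hazard`` maps a stratum to events per person-year; keys may be
    grades, ploidy labels, or ``(grade, ploidy)`` pairs — lookup tries the
    pair, then ploidy, then grade.  ``aneuploid_hazard_multiplier`` scales a
    grade-keyed hazard for aneuploid patients, emulating a within-grade
    ploidy effect.
    """

    seed: int = 0
    n_patients: int = 228
    age_mean: float = 55.0
    age_sd: float = 13.9
    male_fraction: float = 122 / 228
    grade_probs: Sequence[float] = (121 / 228, 47 / 228, 32 / 228, 28 / 228)
    ploidy_given_grade: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_PLOIDY_GIVEN_GRADE))
    annual_hazard: Mapping = field(
        default_factory=lambda: dict(DEFAULT_ANNUAL_HAZARD))
    aneuploid_hazard_multiplier: float = 1.0
    other_death_hazard: float = 0.01
    followup_range_years: tuple[float, float] = (5.0, 9.6)
    early_transform_fraction: float = 0.0
    multi_biopsy_prob: float = 25 / 228
    extra_biopsy_counts: Mapping[int, float] = field(
        default_factory=lambda: {2: 10, 3: 10, 4: 3, 7: 2})
    inclusion_start: date = date(2004, 1, 1)
    inclusion_years: float = 3.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        gp = np.asarray(self.grade_probs, dtype=float)
        if gp.shape != (4,) or abs(gp.sum() - 1.0) > 1e-9 or np.any(gp < 0):
            raise ConfigError("grade_probs must be a non-negative 4-vector summing to 1")
        for g in GRADES:
            row = np.asarray(self.ploidy_given_grade[g], dtype=float)
            if row.shape != (3,) or abs(row.sum() - 1.0) > 1e-9 or np.any(row < 0):
                raise ConfigError(
                    f"ploidy_given_grade[{g!r}] must be a probability 3-vector")
        for k, h in self.annual_hazard.items():
            if h < 0:
                raise ConfigError(f"annual_hazard[{k!r}] must be >= 0, got {h}")
        lo, hi = self.followup_range_years
        if not (0 < lo <= hi):
            raise ConfigError("followup_range_years must be a positive interval")
        if not 0.0 <= self.early_transform_fraction <= 1.0:
            raise ConfigError("early_transform_fraction must lie in [0, 1]")
        if not 0.0 <= self.multi_biopsy_prob <= 1.0:
            raise ConfigError("multi_biopsy_prob must lie in [0, 1]")
        if self.other_death_hazard < 0:
            raise ConfigError("other_death_hazard must be >= 0")


def _hazard_for(cfg: CohortSimConfig, grade: str, ploidy: str) -> float:
    hz = cfg.annual_hazard
    if (grade, ploidy) in hz:
        return float(hz[(grade, ploidy)])
    if ploidy in hz:
        return float(hz[ploidy])
    base = float(hz.get(grade, 0.0))
    if ploidy == "aneuploid":
        base *= cfg.aneuploid_hazard_multiplier
    return base


def _years_after(d: date, years: float) -> date:
    return d + timedelta(days=round(years * DAYS_PER_YEAR))


def simulate_cohort(config: CohortSimConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Per patient: grade ~ ``grade_probs``; ploidy ~ ``ploidy_given_grade``;
    transformation time ~ Exponential(stratum hazard); death from other
    causes ~ Exponential(``other_death_hazard``); administrative censoring
    uniform on ``followup_range_years``.  The earliest of the three times
    sets the outcome.  When ``early_transform_fraction`` > 0, that share of
    the observed events is resampled uniformly below 0.5 years (emulating
    carcinomas already present but missed at index biopsy).  Repeat
    biopsies, drawn with ``multi_biopsy_prob``, are placed before the worst
    biopsy with grades no worse than the patient's worst.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    grade_idx = rng.choice(4, size=n, p=np.asarray(config.grade_probs, float))
    ploidy_idx = np.zeros(n, dtype=int)
    for gi, g in enumerate(GRADES):
        mask = grade_idx == gi
        if mask.any():
            ploidy_idx[mask] = rng.choice(
                3, size=int(mask.sum()), p=np.asarray(config.ploidy_given_grade[g], float))

    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18.0, 95.0)
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")

    hazards = np.array([_hazard_for(config, GRADES[gi], PLOIDY_LABELS[pi])
                        for gi, pi in zip(grade_idx, ploidy_idx)])
    with np.errstate(divide="ignore"):
        event_t = np.where(hazards > 0,
                           rng.exponential(1.0, size=n) / np.where(hazards > 0, hazards, 1.0),
                           np.inf)
    censor_t = rng.uniform(*config.followup_range_years, size=n)
    if config.other_death_hazard > 0:
        death_t = rng.exponential(1.0 / config.other_death_hazard, size=n)
    else:
        death_t = np.full(n, np.inf)

    observed = event_t <= np.minimum(censor_t, death_t)
    if config.early_transform_fraction > 0 and observed.any():
        obs_idx = np.flatnonzero(observed)
        k = int(round(config.early_transform_fraction * len(obs_idx)))
        forced = rng.choice(obs_idx, size=k, replace=False)
        event_t[forced] = rng.uniform(0.0, 0.5, size=k)

    index_offsets = rng.uniform(0, config.inclusion_years * DAYS_PER_YEAR, size=n)
    multi = rng.random(n) < config.multi_biopsy_prob
    extra_keys = sorted(config.extra_biopsy_counts)
    extra_w = np.array([config.extra_biopsy_counts[k] for k in extra_keys], float)
    extra_w = extra_w / extra_w.sum()

    patients: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:05d}"
        grade = GRADES[grade_idx[i]]
        ploidy = PLOIDY_LABELS[ploidy_idx[i]]
        worst_date = config.inclusion_start + timedelta(days=float(index_offsets[i]))
        biopsies = [BiopsyRecord(pid, f"{pid}-B1", worst_date, grade, ploidy)]
        if multi[i]:
            n_biopsies = int(extra_keys[rng.choice(len(extra_keys), p=extra_w)])
            back = np.sort(rng.uniform(10.0, 700.0, size=n_biopsies - 1))[::-1]
            for j, days_back in enumerate(back):
                g_extra = GRADES[int(rng.integers(0, grade_idx[i] + 1))]
                p_extra = PLOIDY_LABELS[int(rng.choice(
                    3, p=np.asarray(config.ploidy_given_grade[g_extra], float)))]
                biopsies.append(BiopsyRecord(
                    pid, f"{pid}-B{j + 2}",
                    worst_date - timedelta(days=float(days_back)),
                    g_extra, p_extra))
        # outcomes are clocked from the latest biopsy so every endpoint
        # postdates every biopsy regardless of which one an axis indexes
        anchor = max(b.date for b in biopsies)

        t_event, t_censor, t_death = event_t[i], censor_t[i], death_t[i]
        transformation = None
        death = None
        cause = "none"
        if t_event <= min(t_censor, t_death):
            transformation = _years_after(anchor, float(t_event))
        elif t_death < t_censor:
            death = _years_after(anchor, float(t_death))
            cause = "other"
        last_fu = _years_after(anchor, float(t_censor))
        patients.append(PatientRecord(
            pid, float(round(ages[i], 1)), str(sexes[i]), biopsies, last_fu,
            transformation, death, cause))
    return patients


# ---------------------------------------------------------------------------
# I/O: a cohort directory holds patients.csv + biopsies.csv; a single
# denormalised CSV (one row per biopsy, patient columns repeated) is also
# readable.  Dates are ISO-8601.

_PATIENT_COLS = ["patient_id", "age_at_index", "sex", "last_followup_date",
                 "transformation_date", "death_date", "death_cause"]
_BIOPSY_COLS = ["patient_id", "biopsy_id", "date", "grade", "ploidy"]


def _fmt_date(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def _parse_date(value, where: str, required: bool = False) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if required:
            raise ParseError(f"{where}: missing required date")
        return None
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ParseError(f"{where}: bad date string {value!r}") from exc


def export_cohort(patients: Sequence[PatientRecord], path: str | Path) -> None:
    """Write ``patients.csv`` and ``biopsies.csv`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prows = [{
        "patient_id": p.patient_id,
        "age_at_index": p.age_at_index,
        "sex": p.sex,
        "last_followup_date": _fmt_date(p.last_followup_date),
        "transformation_date": _fmt_date(p.transformation_date),
        "death_date": _fmt_date(p.death_date),
        "death_cause": p.death_cause,
    } for p in patients]
    brows = [{
        "patient_id": b.patient_id, "biopsy_id": b.biopsy_id,
        "date": b.date.isoformat(), "grade": b.grade, "ploidy": b.ploidy,
    } for p in patients for b in p.biopsies]
    pd.DataFrame(prows, columns=_PATIENT_COLS).to_csv(path / "patients.csv", index=False)
    pd.DataFrame(brows, columns=_BIOPSY_COLS).to_csv(path / "biopsies.csv", index=False)


def export_cohort_flat(patients: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a single denormalised CSV, one row per biopsy."""
    rows = [{
        "patient_id": p.patient_id, "biopsy_id": b.biopsy_id,
        "date": b.date.isoformat(), "grade": b.grade, "ploidy": b.ploidy,
        "age_at_index": p.age_at_index, "sex": p.sex,
        "last_followup_date": _fmt_date(p.last_followup_date),
        "transformation_date": _fmt_date(p.transformation_date),
        "death_date": _fmt_date(p.death_date), "death_cause": p.death_cause,
    } for p in patients for b in p.biopsies]
    pd.DataFrame(rows, columns=_BIOPSY_COLS[:2] + ["date", "grade", "ploidy"]
                 + _PATIENT_COLS[1:]).to_csv(path, index=False)


def import_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort from a directory (two tables) or one denormalised CSV."""
    path = Path(path)
    if path.is_dir():
        pdf = pd.read_csv(path / "patients.csv", dtype=str, keep_default_na=False)
        bdf = pd.read_csv(path / "biopsies.csv", dtype=str, keep_default_na=False)
    else:
        flat = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _BIOPSY_COLS if c not in flat.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        bdf = flat[_BIOPSY_COLS]
        pdf = flat[_PATIENT_COLS].drop_duplicates("patient_id")

    biopsies_by_patient: dict[str, list[BiopsyRecord]] = {}
    for i, row in bdf.iterrows():
        where = f"biopsies row {i + 2}"
        d = _parse_date(row["date"], where, required=True)
        try:
            rec = BiopsyRecord(row["patient_id"], row["biopsy_id"], d,
                               row["grade"], row["ploidy"])
        except ConfigError as exc:
            raise ParseError(f"{where}: {exc}") from exc
        biopsies_by_patient.setdefault(row["patient_id"], []).append(rec)

    patients: list[PatientRecord] = []
    for i, row in pdf.iterrows():
        where = f"patients row {i + 2}"
        pid = row["patient_id"]
        if pid not in biopsies_by_patient:
            raise ParseError(f"{where}: patient {pid!r} has no biopsies")
        try:
            age = float(row["age_at_index"])
        except ValueError as exc:
            raise ParseError(f"{where}: bad age {row['age_at_index']!r}") from exc
        patients.append(PatientRecord(
            pid, age, row["sex"], biopsies_by_patient[pid],
            _parse_date(row["last_followup_date"], where, required=True),
            _parse_date(row["transformation_date"], where),
            _parse_date(row["death_date"], where),
            row["death_cause"] or "none"))
    return patients
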