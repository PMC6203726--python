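"""Shared fixtures and hypothesis settings."""

from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import HealthCheck, settings

from ploidyrisk.cohort import BiopsyRecord, PatientRecord

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DAY = timedelta(days=1)


def make_patient(pid: str = "P1",
                 biopsies: list[tuple[str, str, str]] | None = None,
                 transformation: date | None = None,
                 death: date | None = None,
                 death_cause: str = "none",
                 followup: date = date(2012, 6, 1),
                 age: float = 55.0,
                 sex: str = "female") -> PatientRecord:
    """Build a patient from (iso-date, grade, ploidy) biopsy triples."""
    if biopsies is None:
        biopsies = [("2004-03-01", "none", "diploid")]
    recs = [BiopsyRecord(pid, f"{pid}-B{i + 1}", date.fromisoformat(d), g, p)
            for i, (d, g, p) in enumerate(biopsies)]
    return PatientRecord(pid, age, sex, recs, followup, transformation,
                         death, death_cause)


@pytest.fixture
def simple_patient() -> PatientRecord:
    return make_patient()
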