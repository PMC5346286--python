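"""Shared fixtures: compact day-offset record builders and reference rows."""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

import pytest

from odacta.cohort import Diagnosis, PatientRecord, Prescription, Procedure

#: all day offsets in the toy records count from here
BASE = dt.date(2000, 1, 1)


def day(offset: int) -> dt.date:
    return BASE + dt.timedelta(days=offset)


def rx(drug: str, dose: float, start_day: int, supply: int,
       drug_class: str | None = None) -> Prescription:
    if drug_class is None:
        drug_class = {"finasteride": "5ARI", "dutasteride": "5ARI",
                      "sildenafil": "PDE5I"}.get(drug, "NSAID")
    return Prescription(drug, drug_class, dose, day(start_day), supply)


def make_record(
    patient_id: str = "P1",
    *,
    sex: str = "M",
    age_years: float = 45.0,
    encounters: list[int] = (0, 100, 900),
    diagnoses: list[tuple[str, int]] = (),
    prescriptions: list[Prescription] = (),
    procedures: list[tuple[str, int]] = (),
) -> PatientRecord:
    birth = BASE - dt.timedelta(days=int(age_years * 365.25))
    return PatientRecord(
        patient_id=patient_id, sex=sex, birth_date=birth,
        encounters=[day(e) for e in encounters],
        diagnoses=[Diagnosis(code, day(d)) for code, d in diagnoses],
        prescriptions=list(prescriptions),
        procedures=[Procedure(code, day(d)) for code, d in procedures],
    )


@pytest.fixture(scope="session")
def reference_rows() -> list[dict]:
    """Frozen, independently verified effect-metric rows (published
    reference values for the 2x2 arithmetic regression check)."""
    path = Path(__file__).parent / "data" / "reference_screen_rows.csv"
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    for r in rows:
        for k in ("a", "b", "c", "total", "rr_decimals", "ess_print_discrepant"):
            r[k] = int(r[k])
        for k in ("nnh", "risk_ratio", "specificity", "sensitivity",
                  "npv", "ppv", "ess"):
            r[k] = float(r[k])
    return rows
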