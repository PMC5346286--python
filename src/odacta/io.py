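"""Reading and writing the four-table EMR bundle.

The bundle is four CSV files with ISO-8601 dates:

- ``patients.csv``:      patient_id, sex, birth_date
- ``prescriptions.csv``: patient_id, drug, class, daily_dose_mg, start_date, days_supply
- ``diagnoses.csv``:     patient_id, code, date
- ``encounters.csv``:    patient_id, date

Procedure codes share ``diagnoses.csv`` under the ``CPT:`` namespace.
A ``truth.json`` with planted parameters and leaf assignments may sit
alongside a synthetic bundle.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import pandas as pd

from .cohort import Diagnosis, PatientRecord, Prescription, Procedure

BUNDLE_FILES = ("patients.csv", "prescriptions.csv", "diagnoses.csv", "encounters.csv")


def write_emr_bundle(records: list[PatientRecord], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients, scripts, dxs, encs = [], [], [], []
    for r in records:
        patients.append({"patient_id": r.patient_id, "sex": r.sex,
                         "birth_date": r.birth_date.isoformat()})
        for p in r.prescriptions:
            scripts.append({"patient_id": r.patient_id, "drug": p.drug,
                            "class": p.drug_class, "daily_dose_mg": p.daily_dose_mg,
                            "start_date": p.start.isoformat(),
                            "days_supply": p.days_supply})
        for d in r.diagnoses:
            dxs.append({"patient_id": r.patient_id, "code": d.code,
                        "date": d.date.isoformat()})
        for pr in r.procedures:
            dxs.append({"patient_id": r.patient_id, "code": pr.code,
                        "date": pr.date.isoformat()})
        for e in r.encounters:
            encs.append({"patient_id": r.patient_id, "date": e.isoformat()})
    pd.DataFrame(patients, columns=["patient_id", "sex", "birth_date"]).to_csv(
        outdir / "patients.csv", index=False)
    pd.DataFrame(scripts, columns=["patient_id", "drug", "class", "daily_dose_mg",
                                   "start_date", "days_supply"]).to_csv(
        outdir / "prescriptions.csv", index=False)
    pd.DataFrame(dxs, columns=["patient_id", "code", "date"]).to_csv(
        outdir / "diagnoses.csv", index=False)
    pd.DataFrame(encs, columns=["patient_id", "date"]).to_csv(
        outdir / "encounters.csv", index=False)


def _parse_date(s: str, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(s))
    except ValueError as exc:
        raise ValueError(f"malformed date {s!r} in {context}") from exc


def read_emr_bundle(indir) -> list[PatientRecord]:
    indir = Path(indir)
    pat = pd.read_csv(indir / "patients.csv", dtype=str)
    rx = pd.read_csv(indir / "prescriptions.csv", dtype=str)
    dx = pd.read_csv(indir / "diagnoses.csv", dtype=str)
    enc = pd.read_csv(indir / "encounters.csv", dtype=str)

    records: dict[str, PatientRecord] = {}
    for i, row in pat.iterrows():
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id, sex=row.sex,
            birth_date=_parse_date(row.birth_date, f"patients.csv row {i}"))
    for i, row in rx.iterrows():
        records[row.patient_id].prescriptions.append(Prescription(
            drug=row.drug, drug_class=row["class"],
            daily_dose_mg=float(row.daily_dose_mg),
            start=_parse_date(row.start_date, f"prescriptions.csv row {i}"),
            days_supply=int(row.days_supply)))
    for i, row in dx.iterrows():
        date = _parse_date(row.date, f"diagnoses.csv row {i}")
        if str(row.code).startswith("CPT:"):
            records[row.patient_id].procedures.append(Procedure(row.code, date))
        else:
            records[row.patient_id].diagnoses.append(Diagnosis(row.code, date))
    for i, row in enc.iterrows():
        records[row.patient_id].encounters.append(
            _parse_date(row.date, f"encounters.csv row {i}"))
    for r in records.values():
        r.encounters.sort()
        r.diagnoses.sort(key=lambda d: d.date)
        r.prescriptions.sort(key=lambda p: p.start)
    return list(records.values())


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
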