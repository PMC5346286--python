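"""EMR cohort construction and adverse-event case definitions.

This module turns raw EMR-style records (demographics, encounters, dated
diagnosis codes, prescriptions with daily dose and days of supply,
procedures) into a one-row-per-subject analysis table for a chosen
outcome:

- **new ED** — earliest erectile-dysfunction diagnosis after first
  5α-reductase-inhibitor (5α-RI) exposure, in 1998 or later, with a
  contemporaneous phosphodiesterase-5-inhibitor (PDE5I) prescription, and
  no ED / low-libido / PDE5I history before first exposure (a trigger-tool
  case definition: diagnosis + antidote);
- **new low libido** — earliest decreased-libido diagnosis after first
  exposure, same history exclusions;
- **persistent ED (PED)** — new ED documented as still present at least
  90 days after stopping the 5α-RI ("stopping" = end of the last supply
  interval).

Exposure duration is the total length of the union of half-open supply
intervals ``[start, start + days_supply)``, with exact duplicate
prescriptions counted once and gaps contributing zero, truncated at event
onset for cases.  All dates are compared as whole days; intervals are
half-open throughout.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

# ---------------------------------------------------------------------------
# toy code dictionary and drug metadata

#: diagnosis-concept -> ICD-9-style code sets; procedure concepts use the
#: "CPT:" namespace so they can share the diagnoses table of the EMR bundle.
DEFAULT_CODES: dict[str, set[str]] = {
    "ed": {"607.84", "V41.7"},
    "ed_resolved": {"607.84R"},
    "low_libido": {"799.81"},
    "prostate_disease": {"600.00", "600.01"},
    "prostate_cancer": {"185"},
    "hypertension": {"401.9"},
    "diabetes": {"250.00"},
    "smoking": {"305.1"},
    "vascular_disease": {"440.9"},
    "depression": {"311"},
    "obesity": {"278.00"},
    "alcoholism": {"303.90"},
    "hsv": {"054.9"},
    "hiv": {"042"},
    "peyronie": {"607.85"},
    "alopecia": {"704.0"},
    "prostate_surgery": {"CPT:55801"},
}

#: drug classes used throughout
ARI_CLASS = "5ARI"
PDE5I_CLASS = "PDE5I"
DRUG_CLASSES = [ARI_CLASS, PDE5I_CLASS, "NSAID", "SSRI", "DIURETIC",
                "CYCLOVIR", "ANDROGEN", "ANTIANDROGEN"]

#: FDA approval dates; drugs approved after Jan 1992 begin exposure
#: assessment at their approval date.
DRUG_APPROVAL: dict[str, dt.date] = {
    "finasteride": dt.date(1992, 6, 19),
    "dutasteride": dt.date(2001, 11, 20),
    "sildenafil": dt.date(1998, 3, 27),
}

DAYS_PER_YEAR = 365.25


class CohortValidationError(ValueError):
    """A malformed record; the message names the offending record."""


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Prescription:
    drug: str
    drug_class: str
    daily_dose_mg: float
    start: dt.date
    days_supply: int

    @property
    def end(self) -> dt.date:
        """Exclusive end of the supply interval."""
        return self.start + dt.timedelta(days=self.days_supply)


@dataclass(frozen=True)
class Diagnosis:
    code: str
    date: dt.date


@dataclass(frozen=True)
class Procedure:
    code: str
    date: dt.date


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    birth_date: dt.date
    encounters: list[dt.date] = field(default_factory=list)
    diagnoses: list[Diagnosis] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    procedures: list[Procedure] = field(default_factory=list)
    labs: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DoseClass:
    """Per-drug dose-class indicators (not mutually exclusive)."""

    low_finasteride: bool   # every finasteride record <= 1.25 mg/day, no dutasteride
    high_finasteride: bool  # any finasteride record > 1.25 mg/day
    dutasteride: bool       # any dutasteride record

    @property
    def label(self) -> str:
        if self.low_finasteride:
            return "low_finasteride"
        if self.high_finasteride:
            return "high_finasteride"
        return "dutasteride"


@dataclass(frozen=True)
class ExposureSummary:
    first_exposure_date: dt.date
    covered_days: int
    last_supply_end: dt.date
    dose_class: DoseClass


@dataclass(frozen=True)
class OutcomeEvents:
    new_ed_date: dt.date | None
    pde5i_dates: list[dt.date]
    new_low_libido_date: dt.date | None
    ped_flag: bool
    ped_persistence_days: int | None
    resolution_date: dt.date | None


# ---------------------------------------------------------------------------
# validation

def validate_record(record: PatientRecord) -> None:
    pid = record.patient_id
    for enc in record.encounters:
        if enc < record.birth_date:
            raise CohortValidationError(f"record {pid}: encounter {enc} before birth")
    for dx in record.diagnoses:
        if dx.date < record.birth_date:
            raise CohortValidationError(f"record {pid}: diagnosis {dx.code} before birth")
    for rx in record.prescriptions:
        if rx.days_supply < 1:
            raise CohortValidationError(f"record {pid}: days_supply {rx.days_supply} < 1")
        if rx.drug_class == ARI_CLASS and rx.daily_dose_mg <= 0:
            raise CohortValidationError(f"record {pid}: non-positive 5α-RI dose")


# ---------------------------------------------------------------------------
# exposure

def classify_dose(prescriptions: list[Prescription]) -> DoseClass:
    """Dose-class indicators from the subject's 5α-RI prescriptions."""
    fin = [p for p in prescriptions
           if p.drug_class == ARI_CLASS and p.drug.lower().startswith("finasteride")]
    duta = any(p.drug_class == ARI_CLASS and p.drug.lower().startswith("dutasteride")
               for p in prescriptions)
    if not fin and not duta:
        raise ConfigError("no 5α-RI prescription to classify")
    high = any(p.daily_dose_mg > 1.25 for p in fin)
    low = bool(fin) and not high and not duta
    return DoseClass(low_finasteride=low, high_finasteride=high, dutasteride=duta)


def _clip_start(rx: Prescription, approval: dict[str, dt.date]) -> dt.date:
    app = approval.get(rx.drug.lower())
    return max(rx.start, app) if app else rx.start


def exposure_summary(
    prescriptions: list[Prescription],
    drug_class: str = ARI_CLASS,
    truncate_at: dt.date | None = None,
    *,
    approval_dates: dict[str, dt.date] = DRUG_APPROVAL,
) -> ExposureSummary | None:
    """Union-of-supply-intervals exposure duration for one drug class.

    ``covered_days`` is the total length of the union of half-open
    intervals ``[start, start + days_supply)``, intersected with
    ``[first_start, truncate_at)``.  Exact duplicate prescriptions count
    once; gaps between supply intervals contribute zero.
    ``last_supply_end`` is the (untruncated) end of the last supply
    interval — the operative "stopping" date.  Returns ``None`` when the
    subject has no prescription of the class (distinct from zero days).
    """
    scripts = sorted(
        {(p.drug, p.daily_dose_mg, p.start, p.days_supply): p
         for p in prescriptions if p.drug_class == drug_class}.values(),
        key=lambda p: (p.start, p.days_supply),
    )
    if not scripts:
        return None
    intervals = []
    for p in scripts:
        s = _clip_start(p, approval_dates)
        e = p.start + dt.timedelta(days=p.days_supply)
        if e > s:
            intervals.append((s.toordinal(), e.toordinal()))
    if not intervals:
        return None
    intervals.sort()
    first = intervals[0][0]
    last_end = max(e for _, e in intervals)
    hi = min(truncate_at.toordinal(), last_end) if truncate_at else last_end
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += min(cur_e, hi) - min(cur_s, hi)
            cur_s, cur_e = s, e
    covered += min(cur_e, hi) - min(cur_s, hi)
    covered = max(covered, 0)
    return ExposureSummary(
        first_exposure_date=dt.date.fromordinal(first),
        covered_days=int(covered),
        last_supply_end=dt.date.fromordinal(last_end),
        dose_class=classify_dose(scripts),
    )


# ---------------------------------------------------------------------------
# history helpers

def _code_dates(record: PatientRecord, concept: str, codes: dict[str, set[str]]):
    wanted = codes[concept]
    dates = [dx.date for dx in record.diagnoses if dx.code in wanted]
    if concept == "prostate_surgery":
        dates += [pr.date for pr in record.procedures if pr.code in wanted]
    return sorted(dates)


def _class_dates(record: PatientRecord, drug_class: str) -> list[dt.date]:
    return sorted(p.start for p in record.prescriptions if p.drug_class == drug_class)


def _has_prior_dysfunction(record: PatientRecord, before: dt.date,
                           codes: dict[str, set[str]]) -> bool:
    """ED diagnosis, low-libido diagnosis, or PDE5I use strictly before a date."""
    return (
        any(d < before for d in _code_dates(record, "ed", codes))
        or any(d < before for d in _code_dates(record, "low_libido", codes))
        or any(d < before for d in _class_dates(record, PDE5I_CLASS))
    )


def _age_at(record: PatientRecord, when: dt.date) -> float:
    return (when - record.birth_date).days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# eligibility filters

def select_eligible(
    records: list[PatientRecord],
    min_age: float = 16,
    max_age: float = 89,
    window: tuple[dt.date, dt.date] | None = None,
) -> list[PatientRecord]:
    """Men with >=1 encounter and >=1 diagnosis in the window, aged
    ``min_age``..``max_age`` (inclusive) as of their last encounter."""
    out = []
    for r in records:
        validate_record(r)
        if r.sex != "M":
            continue
        encs = [e for e in r.encounters
                if window is None or window[0] <= e <= window[1]]
        dxs = [d for d in r.diagnoses
               if window is None or window[0] <= d.date <= window[1]]
        if not encs or not dxs:
            continue
        age = _age_at(r, max(encs))
        if min_age <= age <= max_age:
            out.append(r)
    return out


def select_young_finasteride_cohort(
    records: list[PatientRecord],
    min_age: float = 16,
    max_age: float = 42,
    codes: dict[str, set[str]] = DEFAULT_CODES,
) -> list[PatientRecord]:
    """The young low-dose-finasteride subcohort.

    Keeps men aged ``min_age``..``max_age`` at first finasteride
    prescription, exposed only to finasteride <= 1.25 mg/day (no
    high-dose finasteride, no dutasteride), with no prostate disease,
    prostate surgery or prostate cancer, and no ED / low-libido / PDE5I
    history before first finasteride exposure.
    """
    out = []
    for r in records:
        fins = [p for p in r.prescriptions
                if p.drug_class == ARI_CLASS and p.drug.lower().startswith("finasteride")]
        if not fins:
            continue
        dose = classify_dose(r.prescriptions)
        if not dose.low_finasteride:
            continue
        first = min(_clip_start(p, DRUG_APPROVAL) for p in fins)
        if not (min_age <= _age_at(r, first) <= max_age):
            continue
        if (_code_dates(r, "prostate_disease", codes)
                or _code_dates(r, "prostate_cancer", codes)
                or _code_dates(r, "prostate_surgery", codes)):
            continue
        if _has_prior_dysfunction(r, first, codes):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# case definitions

def detect_new_ed(
    record: PatientRecord,
    pde5i_window_days: int = 90,
    codes: dict[str, set[str]] = DEFAULT_CODES,
    *,
    es: ExposureSummary | None = None,
) -> dt.date | None:
    """Earliest qualifying new-ED date, or None.

    Qualifies when the ED diagnosis is strictly after first 5α-RI
    exposure, in 1998 or later, within ``pde5i_window_days`` of some
    PDE5I prescription, and the subject has no ED / PDE5I / low-libido
    history before first exposure.
    """
    if es is None:
        es = exposure_summary(record.prescriptions)
    if es is None:
        return None
    first = es.first_exposure_date
    if _has_prior_dysfunction(record, first, codes):
        return None
    pde5i = _class_dates(record, PDE5I_CLASS)
    for d in _code_dates(record, "ed", codes):
        if d <= first or d.year < 1998:
            continue
        if any(abs((d - p).days) <= pde5i_window_days for p in pde5i):
            return d
    return None


def detect_new_low_libido(
    record: PatientRecord,
    codes: dict[str, set[str]] = DEFAULT_CODES,
    *,
    es: ExposureSummary | None = None,
) -> dt.date | None:
    """Earliest low-libido diagnosis after first exposure, clean history."""
    if es is None:
        es = exposure_summary(record.prescriptions)
    if es is None:
        return None
    first = es.first_exposure_date
    if _has_prior_dysfunction(record, first, codes):
        return None
    for d in _code_dates(record, "low_libido", codes):
        if d > first:
            return d
    return None


def detect_ped(
    record: PatientRecord,
    min_persistence_days: int = 90,
    pde5i_window_days: int = 90,
    codes: dict[str, set[str]] = DEFAULT_CODES,
    *,
    es: ExposureSummary | None = None,
) -> OutcomeEvents:
    """Persistent-ED determination for a subject with detected new ED.

    ``ped_flag`` requires positive documentation of persistence: the
    latest ED-supporting diagnosis date must fall at least
    ``min_persistence_days`` after stopping (end of last supply
    interval), and the ED must either lack a resolution record or resolve
    at least that long after stopping.  ``ped_persistence_days`` runs
    from stopping to resolution (if any) else to the last ED
    documentation.
    """
    if es is None:
        es = exposure_summary(record.prescriptions)
    ed_date = detect_new_ed(record, pde5i_window_days, codes, es=es)
    if ed_date is None:
        raise ValueError(f"record {record.patient_id}: PED requires detected new ED")
    stop = es.last_supply_end
    ed_docs = [d for d in _code_dates(record, "ed", codes) if d >= ed_date]
    last_doc = max(ed_docs)
    resolutions = [d for d in _code_dates(record, "ed_resolved", codes) if d >= ed_date]
    resolution = min(resolutions) if resolutions else None
    unresolved_long = resolution is None or (resolution - stop).days >= min_persistence_days
    documented_long = (last_doc - stop).days >= min_persistence_days
    flag = bool(unresolved_long and documented_long)
    endpoint = resolution if resolution is not None else last_doc
    persistence = (endpoint - stop).days
    return OutcomeEvents(
        new_ed_date=ed_date,
        pde5i_dates=_class_dates(record, PDE5I_CLASS),
        new_low_libido_date=detect_new_low_libido(record, codes, es=es),
        ped_flag=flag,
        ped_persistence_days=persistence,
        resolution_date=resolution,
    )


def outcome_events(
    record: PatientRecord,
    min_persistence_days: int = 90,
    pde5i_window_days: int = 90,
    codes: dict[str, set[str]] = DEFAULT_CODES,
    *,
    es: ExposureSummary | None = None,
) -> OutcomeEvents:
    """Outcome events for any subject (ped_flag False when no new ED)."""
    if es is None:
        es = exposure_summary(record.prescriptions)
    ed_date = detect_new_ed(record, pde5i_window_days, codes, es=es)
    if ed_date is None:
        return OutcomeEvents(
            new_ed_date=None,
            pde5i_dates=_class_dates(record, PDE5I_CLASS),
            new_low_libido_date=detect_new_low_libido(record, codes, es=es),
            ped_flag=False, ped_persistence_days=None, resolution_date=None,
        )
    return detect_ped(record, min_persistence_days, pde5i_window_days, codes, es=es)


# ---------------------------------------------------------------------------
# analysis table

BINARY_DIAGNOSIS_PREDICTORS = [
    "prostate_disease", "prostate_cancer", "hypertension", "diabetes",
    "smoking", "vascular_disease", "depression", "obesity", "alcoholism",
    "hsv", "hiv", "peyronie", "alopecia",
]
BINARY_DRUG_PREDICTORS = {
    "nsaid": "NSAID", "ssri": "SSRI", "diuretic": "DIURETIC",
    "cyclovir": "CYCLOVIR", "androgen": "ANDROGEN", "antiandrogen": "ANTIANDROGEN",
}

OUTCOME_KINDS = ("ED", "low_libido", "PED")


def build_analysis_table(
    records: list[PatientRecord],
    outcome_kind: str = "PED",
    *,
    pde5i_window_days: int = 90,
    min_persistence_days: int = 90,
    codes: dict[str, set[str]] = DEFAULT_CODES,
) -> pd.DataFrame:
    """One row per subject: binary outcome plus the predictor roster.

    Time-varying predictors (age, exposure days, encounter counts) are
    evaluated at event onset for cases and at the last encounter for
    non-cases; exposure days are truncated at the reference date.
    Diagnosis- and drug-based binary predictors use presence anywhere in
    the record, except prostate surgery, which for cases ignores
    procedures after onset.  Lab values (if carried on the record) are
    included as ordered columns with NaN for missing.
    """
    if outcome_kind not in OUTCOME_KINDS:
        raise ConfigError(f"outcome_kind must be one of {OUTCOME_KINDS}")
    lab_names = sorted({k for r in records for k in r.labs})
    rows = []
    for r in records:
        es_full = exposure_summary(r.prescriptions)
        ev = outcome_events(r, min_persistence_days, pde5i_window_days, codes,
                            es=es_full)
        if outcome_kind == "ED":
            event_date = ev.new_ed_date
            outcome = int(event_date is not None)
        elif outcome_kind == "low_libido":
            event_date = ev.new_low_libido_date
            outcome = int(event_date is not None)
        else:
            outcome = int(ev.ped_flag)
            event_date = ev.new_ed_date if ev.ped_flag else None

        is_case = outcome == 1
        ref = event_date if is_case else (max(r.encounters) if r.encounters else None)
        if ref is None:
            continue

        if es_full is not None and (not is_case or ref >= es_full.last_supply_end):
            es = es_full  # truncation past the last supply changes nothing
        else:
            es = exposure_summary(r.prescriptions, truncate_at=ref)
        first_exp = es.first_exposure_date if es else None
        if is_case:
            encs = [e for e in r.encounters if e < ref]
        else:
            encs = list(r.encounters)
        row = {
            "patient_id": r.patient_id,
            "outcome": outcome,
            "age_years": _age_at(r, ref),
            "age_at_first_exposure": (_age_at(r, first_exp)
                                      if first_exp else float("nan")),
            "exposure_days": es.covered_days if es else 0,
            "encounters_total": len(encs),
            "encounters_before_exposure": sum(e < first_exp for e in encs) if first_exp else len(encs),
            "encounters_after_exposure": sum(e >= first_exp for e in encs) if first_exp else 0,
        }
        for name in BINARY_DIAGNOSIS_PREDICTORS:
            row[name] = int(bool(_code_dates(r, name, codes)))
        surg = _code_dates(r, "prostate_surgery", codes)
        if is_case:
            surg = [d for d in surg if d < ref]
        row["prostate_surgery"] = int(bool(surg))
        for col, cls in BINARY_DRUG_PREDICTORS.items():
            row[col] = int(bool(_class_dates(r, cls)))
        if es is not None:
            row["low_finasteride"] = int(es.dose_class.low_finasteride)
            row["high_finasteride"] = int(es.dose_class.high_finasteride)
            row["dutasteride"] = int(es.dose_class.dutasteride)
        else:
            row["low_finasteride"] = row["high_finasteride"] = row["dutasteride"] = 0
        for lab in lab_names:
            row[lab] = r.labs.get(lab, float("nan"))
        rows.append(row)
    columns = (["patient_id", "outcome", "age_years", "age_at_first_exposure",
                "exposure_days", "encounters_total",
                "encounters_before_exposure", "encounters_after_exposure"]
               + BINARY_DIAGNOSIS_PREDICTORS + ["prostate_surgery"]
               + list(BINARY_DRUG_PREDICTORS)
               + ["low_finasteride", "high_finasteride", "dutasteride"]
               + lab_names)
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# temporal holdout

def truncate_record(record: PatientRecord, cutoff: dt.date) -> PatientRecord:
    """Record as it looked on ``cutoff``: drops later-dated content
    (prescriptions are kept if issued by the cutoff; supply may extend past)."""
    return replace(
        record,
        encounters=[e for e in record.encounters if e <= cutoff],
        diagnoses=[d for d in record.diagnoses if d.date <= cutoff],
        prescriptions=[p for p in record.prescriptions if p.start <= cutoff],
        procedures=[p for p in record.procedures if p.date <= cutoff],
    )


def temporal_holdout(
    records: list[PatientRecord],
    cutoff_date: dt.date,
    *,
    holdout_days: int = 183,
    window: tuple[dt.date, dt.date] | None = None,
    codes: dict[str, set[str]] = DEFAULT_CODES,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Prospective-validation split at ``cutoff_date``.

    Train records are truncated at the cutoff.  Holdout records are the
    subjects with no detected sexual dysfunction (new ED or new low
    libido) in the main interval, truncated at ``cutoff + holdout_days``
    so that only events inside the holdout interval count.
    """
    if window is not None and not (window[0] < cutoff_date < window[1]):
        raise ConfigError(f"cutoff {cutoff_date} outside study window {window}")
    train = [truncate_record(r, cutoff_date) for r in records]
    holdout_end = cutoff_date + dt.timedelta(days=holdout_days)
    holdout = []
    for r, tr in zip(records, train):
        if detect_new_ed(tr, codes=codes) or detect_new_low_libido(tr, codes=codes):
            continue
        holdout.append(truncate_record(r, holdout_end))
    return train, holdout


def cohort_flow(records, steps: list[tuple[str, list[PatientRecord]]]) -> dict:
    """Counts at each filter stage, for the cohort-flow log."""
    flow = {"input": len(records)}
    flow.update({name: len(subset) for name, subset in steps})
    return flow
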