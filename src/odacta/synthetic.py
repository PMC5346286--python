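"""Synthetic EMR cohort generation with a planted threshold-tree outcome.

The generator emulates the statistical structure of a large health-system
EMR cohort of men, so the full pipeline — exposure-duration computation,
trigger-tool case definitions, univariable ODA screens and CTA trees —
can be exercised and its parameter recovery tested without any external
data.  It produces :class:`~odacta.cohort.PatientRecord` objects with:

- comorbidity and co-medication prevalences per exposure stratum
  (defaults: published baseline characteristics of the emulated cohort,
  e.g. prescription-NSAID use 26.8% unexposed / 55.8% exposed);
- log-normal ages fitted to each stratum's median/IQR (positive skew);
- 5α-RI prescription episodes as (start, days-of-supply) pairs with
  gaps, deliberate overlaps and occasional exact duplicates, so the
  union-of-intervals duration algorithm is exercised;
- a planted threshold tree that maps each exposed subject to a leaf-level
  ED risk, persistent-ED draws given ED (persistence days log-normal,
  default median 1,348 days), and structured resolution codes for
  transient ED.

Planted event chronology: ED onset is drawn shortly *after* the end of
the last supply interval, the contemporaneous PDE5I prescription within
±30 days of onset, and either a resolution code within 90 days of
stopping (transient) or a final ED-documentation code at stop +
persistence (persistent).  Outcome draws use a random stream separate
from cohort generation, so one cohort can host multiple planted models.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (ARI_CLASS, DEFAULT_CODES, DRUG_APPROVAL, PDE5I_CLASS,
                     Diagnosis, PatientRecord, Prescription, Procedure,
                     exposure_summary)


class ConfigError(ValueError):
    pass


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal from a printed median and IQR."""
    mu = math.log(median)
    sigma = math.log(iqr[1] / iqr[0]) / 1.349  # q3 - q1 spans 2 * z_{0.75} sigmas
    return mu, sigma


def _truncated_lognormal(rng, mu: float, sigma: float, lo: float, hi: float,
                         size: int) -> np.ndarray:
    """Log-normal draws restricted to [lo, hi] by inverse-CDF sampling
    (the emulated population is itself age-restricted, so the printed
    median/IQR describe an already-truncated distribution)."""
    from scipy.stats import norm
    a = norm.cdf((math.log(lo) - mu) / sigma)
    b = norm.cdf((math.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


# Per-stratum attribute prevalences (unexposed, all-exposed) from the
# emulated cohort's baseline-characteristics table.
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "nsaid": (0.268, 0.558),
    "hypertension": (0.175, 0.397),
    "smoking": (0.166, 0.324),
    "vascular_disease": (0.132, 0.322),
    "diuretic": (0.090, 0.269),
    "diabetes": (0.067, 0.134),
    "ssri": (0.053, 0.150),
    "depression": (0.051, 0.120),
    "alcoholism": (0.046, 0.031),
    "obesity": (0.045, 0.086),
    "prostate_disease": (0.037, 0.363),
    "prostate_cancer": (0.027, 0.066),
    "cyclovir": (0.026, 0.084),
    "prostate_surgery": (0.019, 0.119),
    "hsv": (0.010, 0.031),
    "alopecia": (0.004, 0.205),
    "peyronie": (0.001, 0.006),
}

_DRUG_ATTRS = {"nsaid": ("ibuprofen", "NSAID", 400.0),
               "ssri": ("sertraline", "SSRI", 50.0),
               "diuretic": ("hydrochlorothiazide", "DIURETIC", 25.0),
               "cyclovir": ("acyclovir", "CYCLOVIR", 400.0)}
# remaining binary attributes are diagnosis codes (or a procedure)
_DX_ATTRS = ["hypertension", "smoking", "vascular_disease", "diabetes",
             "depression", "alcoholism", "obesity", "prostate_disease",
             "prostate_cancer", "hsv", "alopecia", "peyronie"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    ``age_distribution`` holds (median-years, (q1, q3)) per stratum;
    ``duration_model`` is (median-days, log-sd) of total covered 5α-RI
    exposure; ``dose_mix`` the probabilities of low-dose finasteride
    (<=1.25 mg/day), high-dose finasteride, and dutasteride.
    """

    n_subjects: int = 1000
    exposure_fraction: float = 0.025
    attribute_prevalences: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_distribution: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: {
            "unexposed": (38.9, (28.7, 53.6)),
            "exposed": (51.0, (30.8, 66.3)),
        })
    duration_model: tuple[float, float] = (168.0, 1.1)
    dose_mix: tuple[float, float, float] = (0.43, 0.46, 0.11)
    episode_supply_choices: tuple[int, ...] = (30, 90)
    episode_supply_probs: tuple[float, ...] = (0.6, 0.4)
    episode_grid_days: int = 15
    episode_gap_mean_days: float = 22.5
    episode_overlap_prob: float = 0.15
    episode_duplicate_prob: float = 0.05
    age_bounds: tuple[float, float] = (16.0, 89.0)
    study_window: tuple[dt.date, dt.date] = (dt.date(1992, 1, 1),
                                             dt.date(2015, 9, 30))
    background_ed_rate: float = 0.021
    background_low_libido_rate: float = 0.008
    prior_dysfunction_rate_exposed: float = 0.105
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.exposure_fraction <= 1.0:
            raise ConfigError("exposure_fraction must be in [0, 1]")
        for name, (pu, pe) in self.attribute_prevalences.items():
            if not (0.0 <= pu <= 1.0 and 0.0 <= pe <= 1.0):
                raise ConfigError(f"prevalence for {name!r} outside [0, 1]")
        if not self.study_window[0] < self.study_window[1]:
            raise ConfigError("study window start must precede end")
        if abs(sum(self.dose_mix) - 1.0) > 1e-9:
            raise ConfigError("dose_mix must sum to 1")


def default_spec(**overrides) -> SyntheticSpec:
    """The default synthetic-cohort specification (validated)."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()


@dataclass(frozen=True)
class PlantedTreeSpec:
    """A planted decision-list outcome model.

    ``nodes`` is an ordered chain of (attribute, cutpoint-or-None,
    continue-branch): at node *i* the condition is ``value > cutpoint``
    (or truth of a binary attribute when cutpoint is None); subjects on
    the branch named by ``continue_branch`` ("true"/"false") proceed to
    the next node, the others exit at leaf ``leaf_i``; survivors of the
    last node land in ``leaf_final``.  ``leaf_risks`` maps every leaf id
    to an ED probability.  ``p_ped_given_ed`` and the log-normal
    ``persistence_model`` (median-days, log-sd) govern persistence.
    """

    nodes: tuple = (
        ("prostate_disease", None, "false"),
        ("exposure_days", 208.5, "true"),
        ("nsaid", None, "true"),
    )
    # ED risk per leaf, scaled to the emulated cohort's new-ED rates
    # (~4.5-5% overall; 7.8% with prostate disease; the high-risk leaf's
    # 2.1% PED rate divided by p_ped_given_ed gives ~6.7% ED).  PED
    # follows as p_ped_given_ed * ED, i.e. ~1.4-1.5% overall.
    leaf_risks: dict[str, float] = field(default_factory=lambda: {
        "leaf_0": 0.078,   # prostate disease
        "leaf_1": 0.020,   # no prostate disease, short exposure
        "leaf_2": 0.030,   # long exposure, no NSAID
        "leaf_final": 0.067,  # long exposure + NSAID
    })
    p_ped_given_ed: float = 0.315
    persistence_model: tuple[float, float] = (1348.0, 0.965)
    low_libido_risk: float = 0.012

    def __post_init__(self) -> None:
        for k, v in self.leaf_risks.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"leaf risk {k}={v} outside [0, 1]")
        expected = {f"leaf_{i}" for i in range(len(self.nodes))} | {"leaf_final"}
        if set(self.leaf_risks) != expected:
            raise ConfigError(f"leaf_risks keys {set(self.leaf_risks)} != {expected}")

    def route(self, attrs: dict[str, float]) -> str:
        """Leaf id for one subject's resolved attribute values."""
        for i, (name, cut, cont) in enumerate(self.nodes):
            if name not in attrs:
                raise ConfigError(f"planted attribute {name!r} unresolvable")
            v = attrs[name]
            cond = bool(v) if cut is None else (v > cut)
            if cond != (cont == "true"):
                return f"leaf_{i}"
        return "leaf_final"


# ---------------------------------------------------------------------------

def _draw_episodes(rng, spec: SyntheticSpec, start: dt.date,
                   target_days: float, drug: str, dose: float,
                   window_end: dt.date) -> list[Prescription]:
    """Prescription episodes whose interval union approximates target_days.

    Refill chronology lives on a ``episode_grid_days`` grid (supplies,
    overlaps and gaps are multiples of it), the cadence real refill
    calendars tend to follow; occasional overlapping starts and exact
    duplicates exercise the downstream union/deduplication logic.
    """
    grid = spec.episode_grid_days
    n_max = max(2, int(target_days / min(spec.episode_supply_choices)) + 2)
    supplies = rng.choice(spec.episode_supply_choices, size=n_max,
                          p=spec.episode_supply_probs)
    overlaps = rng.random(n_max) < spec.episode_overlap_prob
    duplicates = rng.random(n_max) < spec.episode_duplicate_prob
    gaps = (rng.exponential(spec.episode_gap_mean_days, n_max) / grid
            ).astype(np.int64) * grid

    scripts = []
    covered = 0
    cursor = start
    for i in range(n_max):
        supply = int(supplies[i])
        if cursor > window_end:
            break
        scripts.append(Prescription(drug, ARI_CLASS, dose, cursor, supply))
        if duplicates[i]:
            scripts.append(Prescription(drug, ARI_CLASS, dose, cursor, supply))
        if overlaps[i] and supply > grid:
            step = supply - grid  # next refill starts one grid unit early
        else:
            step = supply + int(gaps[i])
        covered += step if overlaps[i] and supply > grid else supply
        cursor = cursor + dt.timedelta(days=step)
        if covered >= target_days:
            break
    return scripts


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> list[PatientRecord]:
    """Generate ``spec.n_subjects`` patient records.

    Deterministic in (spec, seed); exposed subjects receive >=1 5α-RI
    prescription episode inside the study window, and every attribute's
    empirical prevalence converges to its stratum value.
    """
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence([int(seed)])
    rng = np.random.default_rng(ss)
    n = spec.n_subjects
    w0, w1 = spec.study_window
    span_days = (w1 - w0).days

    exposed = rng.random(n) < spec.exposure_fraction
    attr_flags = {}
    for name, (pu, pe) in spec.attribute_prevalences.items():
        p = np.where(exposed, pe, pu)
        attr_flags[name] = rng.random(n) < p

    ages = np.empty(n)
    for stratum, mask in (("unexposed", ~exposed), ("exposed", exposed)):
        med, iqr = spec.age_distribution[stratum]
        mu, sigma = _lognormal_params(med, iqr)
        ages[mask] = _truncated_lognormal(rng, mu, sigma, *spec.age_bounds,
                                          size=int(mask.sum()))

    entry_offset = rng.integers(0, max(1, int(span_days * 0.6)), size=n)
    dur_med, dur_sd = spec.duration_model
    durations = rng.lognormal(math.log(dur_med), dur_sd, size=n)
    dose_idx = rng.choice(3, size=n, p=spec.dose_mix)

    n_enc = np.where(exposed, 3 + rng.poisson(12, n), 1 + rng.poisson(4, n))
    bg_ed = rng.random(n) < spec.background_ed_rate
    bg_ll = rng.random(n) < spec.background_low_libido_rate
    prior_dys = exposed & (rng.random(n) < spec.prior_dysfunction_rate_exposed)

    ed_code = sorted(DEFAULT_CODES["ed"])[0]
    ll_code = sorted(DEFAULT_CODES["low_libido"])[0]
    dose_table = [("finasteride", 1.0), ("finasteride", 5.0), ("dutasteride", 0.5)]
    exposure_floor = dt.date(1998, 1, 1)

    records = []
    for i in range(n):
        entry = w0 + dt.timedelta(days=int(entry_offset[i]))
        birth = entry - dt.timedelta(days=int(ages[i] * 365.25))
        follow_years = float(rng.uniform(1.0, 10.0)) if not exposed[i] else None

        prescriptions: list[Prescription] = []
        diagnoses: list[Diagnosis] = []
        procedures: list[Procedure] = []

        if exposed[i]:
            drug, dose = dose_table[dose_idx[i]]
            floor = max(exposure_floor, DRUG_APPROVAL.get(drug, exposure_floor))
            start0 = max(entry, floor) + dt.timedelta(
                days=int(rng.integers(0, 730)))
            latest_start = w1 - dt.timedelta(days=400)
            if start0 > latest_start:
                start0 = latest_start
            scripts = _draw_episodes(rng, spec, start0, durations[i],
                                     drug, dose, w1)
            prescriptions.extend(scripts)
            stop = max(p.end for p in scripts)
            last_date = min(w1, stop + dt.timedelta(days=int(rng.integers(365, 2600))))
        else:
            last_date = min(w1, entry + dt.timedelta(days=int(follow_years * 365.25)))

        span = max((last_date - entry).days, 1)
        enc_days = np.sort(rng.integers(0, span, size=int(n_enc[i])))
        encounters = [entry + dt.timedelta(days=int(d)) for d in enc_days]
        encounters.append(last_date)

        def rand_date():
            return entry + dt.timedelta(days=int(rng.integers(0, span)))

        for name in _DX_ATTRS:
            if attr_flags[name][i]:
                diagnoses.append(Diagnosis(sorted(DEFAULT_CODES[name])[0], rand_date()))
        if attr_flags["prostate_surgery"][i]:
            procedures.append(Procedure(sorted(DEFAULT_CODES["prostate_surgery"])[0],
                                        rand_date()))
        for name, (dname, dcls, ddose) in _DRUG_ATTRS.items():
            if attr_flags[name][i]:
                prescriptions.append(Prescription(dname, dcls, ddose, rand_date(), 30))

        # background sexual dysfunction (pre-exposure for exposed subjects)
        if exposed[i]:
            first_rx = min(p.start for p in prescriptions
                           if p.drug_class == ARI_CLASS)
            if prior_dys[i]:
                back = max((first_rx - entry).days, 1)
                d = entry + dt.timedelta(days=int(rng.integers(0, back)))
                kind = int(rng.integers(0, 3))
                if kind == 0:
                    diagnoses.append(Diagnosis(ed_code, d))
                elif kind == 1:
                    diagnoses.append(Diagnosis(ll_code, d))
                else:
                    prescriptions.append(
                        Prescription("sildenafil", PDE5I_CLASS, 50.0, d, 30))
        else:
            if bg_ed[i]:
                d = rand_date()
                diagnoses.append(Diagnosis(ed_code, d))
                prescriptions.append(
                    Prescription("sildenafil", PDE5I_CLASS, 50.0, d, 30))
            if bg_ll[i]:
                diagnoses.append(Diagnosis(ll_code, rand_date()))

        if not diagnoses:  # eligibility requires >=1 diagnosis
            diagnoses.append(Diagnosis("V70.0", rand_date()))

        records.append(PatientRecord(
            patient_id=f"S{i:07d}", sex="M", birth_date=birth,
            encounters=sorted(encounters), diagnoses=diagnoses,
            prescriptions=prescriptions, procedures=procedures,
        ))
    return records


# ---------------------------------------------------------------------------

@dataclass
class PlantedCohort:
    records: list[PatientRecord]
    leaf_assignments: dict[str, str]      # patient_id -> leaf id (exposed only)
    planted_ed: dict[str, bool]
    planted_ped: dict[str, bool]
    planted_persistence_days: dict[str, int]
    tree: PlantedTreeSpec

    def truth_dict(self) -> dict:
        return {
            "nodes": [list(nd) for nd in self.tree.nodes],
            "leaf_risks": self.tree.leaf_risks,
            "p_ped_given_ed": self.tree.p_ped_given_ed,
            "persistence_model": list(self.tree.persistence_model),
            "leaf_assignments": self.leaf_assignments,
            "planted_ed": {k: bool(v) for k, v in self.planted_ed.items()},
            "planted_ped": {k: bool(v) for k, v in self.planted_ped.items()},
            "planted_persistence_days": self.planted_persistence_days,
        }


def _resolve_attrs(record: PatientRecord) -> dict[str, float] | None:
    """Attribute values the planted tree may reference (exposed only)."""
    es = exposure_summary(record.prescriptions)
    if es is None:
        return None
    attrs: dict[str, float] = {
        "exposure_days": float(es.covered_days),
        "age_years": (max(record.encounters) - record.birth_date).days / 365.25,
    }
    from .cohort import (BINARY_DIAGNOSIS_PREDICTORS, BINARY_DRUG_PREDICTORS,
                         _class_dates, _code_dates)
    for name in BINARY_DIAGNOSIS_PREDICTORS + ["prostate_surgery"]:
        attrs[name] = float(bool(_code_dates(record, name, DEFAULT_CODES)))
    for col, cls in BINARY_DRUG_PREDICTORS.items():
        attrs[col] = float(bool(_class_dates(record, cls)))
    return attrs


def plant_outcome(records: list[PatientRecord], tree: PlantedTreeSpec,
                  seed: int = 0, *,
                  window_end: dt.date = dt.date(2015, 9, 30)) -> PlantedCohort:
    """Assign ED / persistent-ED / low-libido events by leaf-level risk.

    Mutates the records in place (adds diagnosis codes, PDE5I
    prescriptions and documentation encounters) and returns the truth
    set.  Subjects without 5α-RI exposure receive no planted events.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    ed_code = sorted(DEFAULT_CODES["ed"])[0]
    res_code = sorted(DEFAULT_CODES["ed_resolved"])[0]
    ll_code = sorted(DEFAULT_CODES["low_libido"])[0]
    per_med, per_sd = tree.persistence_model

    leaves: dict[str, str] = {}
    p_ed: dict[str, bool] = {}
    p_ped: dict[str, bool] = {}
    p_days: dict[str, int] = {}
    for r in records:
        attrs = _resolve_attrs(r)
        if attrs is None:
            continue
        leaf = tree.route(attrs)
        leaves[r.patient_id] = leaf
        es = exposure_summary(r.prescriptions)
        stop = es.last_supply_end
        ed = bool(rng.random() < tree.leaf_risks[leaf])
        p_ed[r.patient_id] = ed
        if ed:
            onset = stop + dt.timedelta(days=int(rng.integers(1, 46)))
            onset = min(onset, window_end)
            r.diagnoses.append(Diagnosis(ed_code, onset))
            pde5i_start = onset + dt.timedelta(days=int(rng.integers(-30, 31)))
            r.prescriptions.append(
                Prescription("sildenafil", PDE5I_CLASS, 50.0,
                             max(pde5i_start, dt.date(1998, 3, 27)), 30))
            r.encounters.append(onset)
            ped = bool(rng.random() < tree.p_ped_given_ed)
            p_ped[r.patient_id] = ped
            if ped:
                persistence = max(90, int(rng.lognormal(math.log(per_med), per_sd)))
                last_doc = min(stop + dt.timedelta(days=persistence), window_end)
                persistence = (last_doc - stop).days
                r.diagnoses.append(Diagnosis(ed_code, last_doc))
                r.encounters.append(last_doc)
                p_days[r.patient_id] = persistence
            else:
                res = stop + dt.timedelta(days=int(rng.integers(max(
                    10, (onset - stop).days + 1), 81)))
                res = min(res, window_end)
                r.diagnoses.append(Diagnosis(res_code, res))
                r.encounters.append(res)
        else:
            p_ped[r.patient_id] = False
        if rng.random() < tree.low_libido_risk:
            ll = min(stop + dt.timedelta(days=int(rng.integers(1, 91))), window_end)
            r.diagnoses.append(Diagnosis(ll_code, ll))
            r.encounters.append(ll)
        r.encounters.sort()
    return PlantedCohort(records=records, leaf_assignments=leaves,
                         planted_ed=p_ed, planted_ped=p_ped,
                         planted_persistence_days=p_days, tree=tree)
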