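"""Cohort construction: exposure-duration union algorithm, dose classes,
trigger-tool case definitions, eligibility filters, analysis table and
the temporal holdout split."""

import datetime as dt

import numpy as np
import pytest

from conftest import BASE, day, make_record, rx
from odacta.cohort import (CohortValidationError, ConfigError,
                           build_analysis_table, classify_dose, detect_new_ed,
                           detect_new_low_libido, detect_ped,
                           exposure_summary, select_eligible,
                           select_young_finasteride_cohort, temporal_holdout,
                           truncate_record)


def day_by_day_covered(scripts, truncate_at=None):
    """Oracle: scan every calendar day and count covered ones."""
    days = set()
    dedup = {(p.drug, p.daily_dose_mg, p.start, p.days_supply) for p in scripts}
    for drug, dose, start, supply in dedup:
        for k in range(supply):
            days.add(start.toordinal() + k)
    if not days:
        return 0
    first = min(days)
    hi = truncate_at.toordinal() if truncate_at else max(days) + 1
    return sum(1 for d in days if first <= d < hi)


class TestExposureSummary:
    def test_overlapping_scripts_union(self):
        es = exposure_summary([rx("finasteride", 1, 0, 30),
                               rx("finasteride", 1, 15, 30)])
        assert es.covered_days == 45

    def test_gap_contributes_zero(self):
        es = exposure_summary([rx("finasteride", 1, 0, 30),
                               rx("finasteride", 1, 100, 30)],
                              truncate_at=day(200))
        assert es.covered_days == 60

    def test_truncation_at_event_onset(self):
        es = exposure_summary([rx("finasteride", 1, 0, 30)],
                              truncate_at=day(10))
        assert es.covered_days == 10
        assert es.last_supply_end == day(30)

    def test_exact_duplicates_counted_once(self):
        es = exposure_summary([rx("finasteride", 1, 0, 30),
                               rx("finasteride", 1, 0, 30)])
        assert es.covered_days == 30

    def test_no_prescription_of_class_is_distinct_from_zero_days(self):
        assert exposure_summary([rx("ibuprofen", 400, 0, 30)]) is None

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_day_by_day_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scripts = []
        for _ in range(int(rng.integers(1, 8))):
            start = int(rng.integers(0, 400))
            supply = int(rng.integers(1, 120))
            scripts.append(rx("finasteride", 1, start, supply))
        if rng.random() < 0.5:
            scripts.append(scripts[0])  # exact duplicate
        trunc = day(int(rng.integers(0, 600))) if rng.random() < 0.5 else None
        es = exposure_summary(scripts, truncate_at=trunc)
        assert es.covered_days == day_by_day_covered(scripts, trunc)


class TestClassifyDose:
    def test_low_finasteride(self):
        dc = classify_dose([rx("finasteride", 1.0, 0, 30)])
        assert dc.low_finasteride and not dc.high_finasteride
        assert dc.label == "low_finasteride"

    def test_high_finasteride(self):
        dc = classify_dose([rx("finasteride", 5.0, 0, 30)])
        assert dc.high_finasteride and not dc.low_finasteride

    def test_dutasteride(self):
        dc = classify_dose([rx("dutasteride", 0.5, 0, 30)])
        assert dc.dutasteride and dc.label == "dutasteride"

    def test_mixed_low_dose_with_dutasteride_not_low_class(self):
        dc = classify_dose([rx("finasteride", 1.0, 0, 30),
                            rx("dutasteride", 0.5, 50, 30)])
        assert dc.dutasteride and not dc.low_finasteride


EXPOSED = [rx("finasteride", 5.0, 100, 400)]  # supply ends day 500


class TestDetectNewEd:
    def test_all_conditions_met(self):
        r = make_record(diagnoses=[("607.84", 400)],
                        prescriptions=EXPOSED + [rx("sildenafil", 50, 410, 30)])
        assert detect_new_ed(r) == day(400)

    def test_requires_contemporaneous_pde5i(self):
        r = make_record(diagnoses=[("607.84", 400)], prescriptions=EXPOSED)
        assert detect_new_ed(r) is None

    def test_pde5i_before_exposure_excludes(self):
        r = make_record(diagnoses=[("607.84", 400)],
                        prescriptions=EXPOSED + [rx("sildenafil", 50, 50, 30),
                                                 rx("sildenafil", 50, 410, 30)])
        assert detect_new_ed(r) is None

    def test_adding_pre_exposure_ed_code_only_removes(self):
        """Case designations are monotone in history."""
        r = make_record(diagnoses=[("607.84", 400)],
                        prescriptions=EXPOSED + [rx("sildenafil", 50, 410, 30)])
        assert detect_new_ed(r) is not None
        r.diagnoses.append(type(r.diagnoses[0])("607.84", day(50)))
        assert detect_new_ed(r) is None


class TestDetectNewLowLibido:
    def test_code_after_exposure(self):
        r = make_record(diagnoses=[("799.81", 300)],
                        prescriptions=[rx("finasteride", 1, 100, 90)])
        assert detect_new_low_libido(r) == day(300)

    def test_code_before_exposure_excludes(self):
        r = make_record(diagnoses=[("799.81", 50)],
                        prescriptions=[rx("finasteride", 1, 100, 90)])
        assert detect_new_low_libido(r) is None

    def test_no_code_none(self):
        r = make_record(prescriptions=[rx("finasteride", 1, 100, 90)])
        assert detect_new_low_libido(r) is None


class TestDetectPed:
    """Supply ends day 500 ('stopping'); the 90-day rule counts from there."""

    def _record(self, diagnoses):
        return make_record(
            encounters=(0, 100, 700),
            diagnoses=diagnoses,
            prescriptions=EXPOSED + [rx("sildenafil", 50, 430, 30)])

    def test_documented_unresolved_150_days_after_stop(self):
        ev = detect_ped(self._record([("607.84", 420), ("607.84", 650)]))
        assert ev.ped_flag is True
        assert ev.ped_persistence_days == 150

    def test_resolution_60_days_after_stop_not_persistent(self):
        ev = detect_ped(self._record([("607.84", 420), ("607.84R", 560)]))
        assert ev.ped_flag is False

    def test_last_documentation_20_days_after_stop_insufficient(self):
        ev = detect_ped(self._record([("607.84", 420), ("607.84", 520)]))
        assert ev.ped_flag is False
        assert ev.ped_persistence_days == 20

    def test_exact_90_day_boundary_is_persistent(self):
        ev = detect_ped(self._record([("607.84", 420), ("607.84", 590)]))
        assert ev.ped_flag is True and ev.ped_persistence_days == 90

    def test_requires_detected_ed(self):
        with pytest.raises(ValueError):
            detect_ped(make_record(prescriptions=EXPOSED))


class TestSelectEligible:
    def _eligible(self, **kw):
        defaults = dict(diagnoses=[("401.9", 10)])
        defaults.update(kw)
        return make_record(**defaults)

    def test_age_15_excluded(self):
        recs = [self._eligible(age_years=13.0)]  # ~15.5 at last encounter
        assert select_eligible(recs) == []

    def test_no_diagnoses_excluded(self):
        assert select_eligible([make_record()]) == []

    def test_identity_on_all_eligible(self):
        recs = [self._eligible(patient_id=f"P{i}") for i in range(5)]
        assert select_eligible(recs) == recs

    def test_idempotent(self):
        recs = [self._eligible(patient_id=f"P{i}", age_years=10.0 + 10 * i)
                for i in range(8)]
        once = select_eligible(recs)
        assert select_eligible(once) == once

    def test_malformed_record_named(self):
        bad = make_record(patient_id="BAD",
                          prescriptions=[rx("finasteride", 1, 0, 0)])
        with pytest.raises(CohortValidationError, match="BAD"):
            select_eligible([bad])


class TestYoungCohort:
    def _young(self, age, scripts, **kw):
        return make_record(age_years=age, prescriptions=scripts,
                           diagnoses=kw.pop("diagnoses", []), **kw)

    def test_43_year_old_excluded(self):
        recs = [self._young(43.0, [rx("finasteride", 1.0, 0, 30)])]
        assert select_young_finasteride_cohort(recs) == []

    def test_dutasteride_script_excludes(self):
        recs = [self._young(30.0, [rx("finasteride", 1.0, 0, 30),
                                   rx("dutasteride", 0.5, 100, 30)])]
        assert select_young_finasteride_cohort(recs) == []

    def test_clean_30_year_old_included(self):
        recs = [self._young(30.0, [rx("finasteride", 1.0, 0, 30)])]
        assert select_young_finasteride_cohort(recs) == recs

    def test_prostate_disease_history_excludes(self):
        recs = [self._young(30.0, [rx("finasteride", 1.0, 0, 30)],
                            diagnoses=[("600.00", 200)])]
        assert select_young_finasteride_cohort(recs) == []


class TestAnalysisTable:
    def test_case_counts_use_pre_onset_encounters_only(self):
        r = make_record(
            encounters=(0, 150, 399, 401, 700),
            diagnoses=[("607.84", 400), ("607.84", 650)],
            prescriptions=EXPOSED + [rx("sildenafil", 50, 410, 30)])
        tab = build_analysis_table([r], "ED")
        assert tab.loc[0, "outcome"] == 1
        assert tab.loc[0, "encounters_total"] == 3  # 0, 150, 399
        assert tab.loc[0, "encounters_after_exposure"] == 2  # 150, 399

    def test_noncase_age_at_last_encounter(self):
        r = make_record(age_years=40.0, encounters=(0, 365),
                        diagnoses=[("401.9", 10)])
        tab = build_analysis_table([r], "ED")
        assert tab.loc[0, "outcome"] == 0
        assert tab.loc[0, "age_years"] == pytest.approx(41.0, abs=0.01)

    def test_case_exposure_truncated_at_onset(self):
        # onset day 200 falls inside the supply interval [100, 500)
        r = make_record(
            diagnoses=[("607.84", 200)],
            prescriptions=EXPOSED + [rx("sildenafil", 50, 210, 30)])
        tab = build_analysis_table([r], "ED")
        assert tab.loc[0, "outcome"] == 1
        assert tab.loc[0, "exposure_days"] == 100  # days 100..199

    def test_empty_cohort_empty_table(self):
        tab = build_analysis_table([], "PED")
        assert len(tab) == 0
        assert "outcome" in tab.columns

    def test_rejects_unknown_outcome_kind(self):
        with pytest.raises(ConfigError):
            build_analysis_table([], "fracture")


class TestTemporalHoldout:
    def _cohort(self):
        def ed_rec(pid, onset):
            return make_record(
                patient_id=pid, encounters=(0, 100, onset, 1400),
                diagnoses=[("607.84", onset)],
                prescriptions=[rx("finasteride", 1, 100, 120),
                               rx("sildenafil", 50, onset, 30)])
        return {
            "early": ed_rec("early", 300),     # event before cutoff
            "soon": ed_rec("soon", 1060),      # ~2 months after cutoff
            "late": ed_rec("late", 1250),      # ~8 months after cutoff
        }

    def test_split_semantics(self):
        recs = self._cohort()
        cutoff = day(1000)
        train, holdout = temporal_holdout(list(recs.values()), cutoff)
        ids = {r.patient_id for r in holdout}
        assert ids == {"soon", "late"}  # 'early' already a case
        hmap = {r.patient_id: r for r in holdout}
        assert detect_new_ed(hmap["soon"]) == day(1060)
        assert detect_new_ed(hmap["late"]) is None  # outside 6-month window
        tmap = {r.patient_id: r for r in train}
        assert detect_new_ed(tmap["early"]) == day(300)

    def test_cutoff_outside_window_rejected(self):
        with pytest.raises(ConfigError):
            temporal_holdout([], day(5000), window=(BASE, day(1000)))

    def test_truncate_record_drops_later_content(self):
        r = self._cohort()["early"]
        t = truncate_record(r, day(200))
        assert max(t.encounters) <= day(200)
        assert all(d.date <= day(200) for d in t.diagnoses)
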