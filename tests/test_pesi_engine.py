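"""Scoring engine: vital extremes, oxygen and mental-status criteria,
total/class computation, and the engine's causal and monotonicity laws."""

from datetime import timedelta

import pytest

import autopesi as ap
from autopesi.ehr_model import VitalKind
from autopesi.pesi_engine import (
    DEFAULT_WEIGHTS,
    altered_mental_status,
    classify,
    compute_pesi,
    oxygen_criterion,
    vital_extremes,
)
from conftest import TRIGGER, make_snapshot, oxygen, problem, vital


class TestVitalExtremes:
    def test_no_samples_all_absent(self):
        ext = vital_extremes([], TRIGGER)
        assert all(v is None for v in ext.values())

    def test_max_hr_selected(self):
        ext = vital_extremes([vital("HR", 80, 90), vital("HR", 115, 30)], TRIGGER)
        assert ext[VitalKind.HR].value == 115

    def test_min_selected_for_sbp_temp_spo2(self):
        samples = [
            vital("SBP", 120, 90), vital("SBP", 95, 30),
            vital("TEMP", 36.5, 90), vital("TEMP", 35.5, 30),
            vital("SPO2", 96, 90), vital("SPO2", 88, 30),
        ]
        ext = vital_extremes(samples, TRIGGER)
        assert ext[VitalKind.SBP].value == 95
        assert ext[VitalKind.TEMP].value == 35.5
        assert ext[VitalKind.SPO2].value == 88

    def test_post_trigger_sample_invisible(self):
        # documentation latency: the adverse reading landed after the trigger
        late_rr = vital("RR", 32, -15)  # 15 minutes AFTER trigger
        early_rr = vital("RR", 18, 60)
        ext = vital_extremes([early_rr, late_rr], TRIGGER)
        assert ext[VitalKind.RR].value == 18


class TestOxygenCriterion:
    def run(self, spo2=None, records=(), home=0.0, **kw):
        samples = [vital("SPO2", spo2, 30)] if spo2 is not None else []
        ext = vital_extremes(samples, TRIGGER)
        return oxygen_criterion(ext, list(records), home, TRIGGER, DEFAULT_WEIGHTS, **kw)

    def test_spo2_below_90_on_room_air(self):
        flag, prov = self.run(spo2=88, records=[oxygen("room_air", 0)])
        assert flag and "SPO2" in prov

    def test_boundary_two_lpm_is_not_flagged(self):
        flag, _ = self.run(spo2=94, records=[oxygen("nasal_cannula", 2.0)])
        assert not flag

    def test_absolute_flow_clause_fires_even_near_home_baseline(self):
        # 4 L/min with a 3 L/min home requirement: home-delta clause is
        # quiet (4 <= 3+2) but the absolute >2 L/min clause fires
        flag, prov = self.run(spo2=93, records=[oxygen("nasal_cannula", 4.0)], home=3.0)
        assert flag and "flow 4" in prov

    def test_suppress_absolute_flow_for_home_oxygen_patients(self):
        flag, _ = self.run(
            spo2=93,
            records=[oxygen("nasal_cannula", 4.0)],
            home=3.0,
            suppress_absolute_flow_when_home_o2=True,
        )
        assert not flag

    def test_flow_above_home_delta(self):
        flag, prov = self.run(spo2=95, records=[oxygen("nasal_cannula", 6.0)], home=3.0)
        assert flag and "home" in prov

    @pytest.mark.parametrize("device", ["bipap", "cpap", "venturi_mask", "high_flow", "ventilator"])
    def test_assist_device_flags(self, device):
        flag, prov = self.run(spo2=95, records=[oxygen(device, 0.0)])
        assert flag and device in prov

    def test_post_trigger_record_invisible(self):
        flag, _ = self.run(spo2=95, records=[oxygen("high_flow", 40.0, minutes_before=-10)])
        assert not flag

    def test_provenance_is_first_qualifying_in_time(self):
        recs = [oxygen("high_flow", 40.0, minutes_before=10), oxygen("nasal_cannula", 5.0, minutes_before=50)]
        flag, prov = self.run(records=recs)
        assert flag and "flow 5" in prov  # the earlier record wins


class TestAlteredMentalStatus:
    def test_normal_gcs_and_complaint(self):
        flag, _ = altered_mental_status([(TRIGGER - timedelta(minutes=10), 15)], ["chest pain"], TRIGGER)
        assert not flag

    def test_gcs_13_flags(self):
        flag, prov = altered_mental_status([(TRIGGER - timedelta(minutes=10), 13)], [], TRIGGER)
        assert flag and "GCS=13" in prov

    def test_post_trigger_gcs_invisible(self):
        flag, _ = altered_mental_status([(TRIGGER + timedelta(minutes=10), 5)], [], TRIGGER)
        assert not flag

    def test_complaint_text_case_insensitive(self):
        flag, prov = altered_mental_status([(TRIGGER, 15)], ["ALTERED MENTAL STATUS"], TRIGGER)
        assert flag and "complaint" in prov

    def test_coded_complaint(self):
        flag, _ = altered_mental_status([], ["419284004"], TRIGGER)
        assert flag


class TestComputePesi:
    def test_score_is_age_for_clean_young_female(self, graph):
        snap = make_snapshot(age_years=18, gcs_records=[], chief_complaints=[])
        res = compute_pesi(snap, graph)
        assert (res.total, res.pesi_class, res.low_risk) == (18, "I", True)
        assert not any(res.component_flags.values())
        assert all(p == "absent" for p in res.provenance.values())

    def test_hand_summed_high_risk_case(self, graph):
        # 60 + male 10 + cancer 30 + HR>=110 20 + SpO2<90 20 = 140
        snap = make_snapshot(
            age_years=60,
            sex_assigned_at_birth="male",
            administrative_sex="male",
            problem_list=[problem("363346000")],
            vitals=[vital("HR", 115), vital("SPO2", 88), vital("SBP", 120),
                    vital("RR", 16), vital("TEMP", 37.0)],
        )
        res = compute_pesi(snap, graph)
        assert res.total == 140
        assert (res.pesi_class, res.low_risk) == ("V", False)
        flagged = {c for c, f in res.component_flags.items() if f}
        assert flagged == {"sex_male", "cancer", "hr_high", "o2_low"}

    def test_every_true_flag_has_provenance(self, graph):
        snap = make_snapshot(
            age_years=70,
            problem_list=[problem("42343007")],
            vitals=[vital("SBP", 85), vital("TEMP", 35.0)],
            gcs_records=[(TRIGGER - timedelta(minutes=5), 12)],
            oxygen_records=[oxygen("bipap", 0.0)],
        )
        res = compute_pesi(snap, graph)
        for comp, flag in res.component_flags.items():
            assert (res.provenance[comp] != "absent") == flag, comp

    def test_deterministic(self, graph):
        snap = make_snapshot(problem_list=[problem("13645005")], vitals=[vital("HR", 112)])
        assert compute_pesi(snap, graph) == compute_pesi(snap, graph)

    def test_sex_fallback_to_administrative(self, graph, caplog):
        snap = make_snapshot(sex_assigned_at_birth="unknown", administrative_sex="male")
        res = compute_pesi(snap, graph)
        assert res.component_flags["sex_male"]
        assert res.total == snap.age_years + 10

    def test_total_at_least_age_and_equality_iff_unflagged(self, graph):
        for snap in [
            make_snapshot(),
            make_snapshot(vitals=[vital("HR", 150)]),
            make_snapshot(sex_assigned_at_birth="male", administrative_sex="male"),
        ]:
            res = compute_pesi(snap, graph)
            assert res.total >= snap.age_years
            assert (res.total == snap.age_years) == (not any(res.component_flags.values()))


class TestClassify:
    @pytest.mark.parametrize(
        "total,expected",
        [(0, ("I", True)), (65, ("I", True)), (66, ("II", True)), (85, ("II", True)),
         (86, ("III", False)), (105, ("III", False)), (106, ("IV", False)),
         (125, ("IV", False)), (126, ("V", False)), (300, ("V", False))],
    )
    def test_boundaries(self, total, expected):
        assert classify(total) == expected

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            classify(-1)

    def test_exhaustive_against_brute_force_table(self):
        for total in range(0, 301):
            if total < 66:
                want = "I"
            elif total <= 85:
                want = "II"
            elif total <= 105:
                want = "III"
            elif total <= 125:
                want = "IV"
            else:
                want = "V"
            cls, low = classify(total)
            assert cls == want
            assert low == (want in ("I", "II"))


class TestEngineLaws:
    def test_monotone_under_adverse_additions(self, graph):
        """Adding any single adverse datum never decreases the total."""
        base = make_snapshot(age_years=55)
        base_total = compute_pesi(base, graph).total
        additions = [
            {"problem_list": [problem("363346000")]},
            {"problem_list": [problem("84114007")]},
            {"problem_list": [problem("13645005")]},
            {"sex_assigned_at_birth": "male", "administrative_sex": "male"},
            {"vitals": [vital("HR", 140)]},
            {"vitals": [vital("SBP", 80)]},
            {"vitals": [vital("RR", 35)]},
            {"vitals": [vital("TEMP", 34.5)]},
            {"vitals": [vital("SPO2", 85)]},
            {"gcs_records": [(TRIGGER - timedelta(minutes=1), 10)]},
            {"oxygen_records": [oxygen("ventilator", 0.0)]},
        ]
        for upd in additions:
            assert compute_pesi(make_snapshot(age_years=55, **upd), graph).total >= base_total

    def test_removing_adverse_vital_never_increases_total(self, graph):
        snap = make_snapshot(vitals=[vital("HR", 140), vital("SBP", 85), vital("SPO2", 80)])
        full = compute_pesi(snap, graph).total
        for drop in range(len(snap.vitals)):
            reduced = snap.model_copy(
                update={"vitals": [s for i, s in enumerate(snap.vitals) if i != drop]}
            )
            assert compute_pesi(reduced, graph).total <= full

    def test_trigger_causality(self, graph):
        """Any datum timestamped after the trigger leaves the result unchanged."""
        snap = make_snapshot(
            age_years=60,
            vitals=[vital("HR", 90), vital("SPO2", 95)],
            problem_list=[problem("13645005")],
        )
        before = compute_pesi(snap, graph)
        after_trigger = snap.model_copy(
            update={
                "vitals": snap.vitals + [vital("HR", 180, -5), vital("SPO2", 70, -60)],
                "problem_list": snap.problem_list + [problem("363346000", days_before=-2)],
                "gcs_records": snap.gcs_records + [(TRIGGER + timedelta(hours=1), 3)],
                "oxygen_records": [oxygen("ventilator", 0.0, minutes_before=-30)],
            }
        )
        assert compute_pesi(after_trigger, graph) == before

    def test_rescoring_at_later_timestamp_sees_late_data(self, graph):
        snap = make_snapshot(age_years=60, vitals=[vital("HR", 90), vital("HR", 120, -5)])
        at_order = compute_pesi(snap, graph)
        later = compute_pesi(snap, graph, trigger=TRIGGER + timedelta(minutes=10))
        assert at_order.total == 60
        assert later.total == 80  # the late tachycardia is now visible
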