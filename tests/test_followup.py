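"""Censoring rules, washout, first-event observation, and a brute-force
day-by-day oracle for follow-up ends."""

import numpy as np
import pandas as pd
import pytest

from iimcohort import StudyConfig
from iimcohort.followup import (
    compute_followup_end,
    observe_events,
    washout_eligibility,
)
from iimcohort.labels import OUTCOMES

from conftest import make_event, make_patient

INDEX = pd.Timestamp("2018-01-01")


def days(n):
    return INDEX + pd.Timedelta(days=n)


class TestFollowupEnd:
    def test_clamped_to_study_end(self, config):
        patient = make_patient(activity_end="2022-06-01")
        fu_end, reason = compute_followup_end(
            "case", INDEX, [], patient, "DM", config
        )
        assert (fu_end, reason) == (config.study_end, "study_end")

    def test_single_inpatient_other_subtype_switches(self, config):
        patient = make_patient()
        events = [make_event(days(100), "PM", "inpatient")]
        fu_end, reason = compute_followup_end(
            "case", INDEX, events, patient, "DM", config
        )
        assert (fu_end, reason) == (days(100), "subtype_switch")

    def test_second_outpatient_other_subtype_switches(self, config):
        patient = make_patient()
        events = [
            make_event(days(50), "PM", "outpatient"),
            make_event(days(80), "PM", "outpatient"),
        ]
        fu_end, reason = compute_followup_end(
            "case", INDEX, events, patient, "DM", config
        )
        assert (fu_end, reason) == (days(80), "subtype_switch")

    def test_single_outpatient_other_subtype_does_not_switch(self, config):
        patient = make_patient()
        events = [make_event(days(50), "PM", "outpatient")]
        fu_end, reason = compute_followup_end(
            "case", INDEX, events, patient, "DM", config
        )
        assert reason == "study_end"

    def test_same_subtype_diagnoses_never_censor_case(self, config):
        patient = make_patient()
        events = [
            make_event(days(10), "DM", "inpatient"),
            make_event(days(20), "DM", "outpatient"),
            make_event(days(30), "DM", "outpatient"),
        ]
        _, reason = compute_followup_end(
            "case", INDEX, events, patient, "DM", config
        )
        assert reason == "study_end"

    def test_control_censored_by_any_single_diagnosis(self, config):
        patient = make_patient()
        events = [make_event(days(30), "DM", "outpatient")]
        fu_end, reason = compute_followup_end(
            "control", INDEX, events, patient, None, config
        )
        assert (fu_end, reason) == (days(30), "control_iim_dx")

    def test_death_beats_activity_end_on_same_day(self, config):
        patient = make_patient(activity_end="2019-01-01",
                               death_date="2019-01-01")
        fu_end, reason = compute_followup_end(
            "case", INDEX, [], patient, "DM", config
        )
        assert (fu_end, reason) == (pd.Timestamp("2019-01-01"), "death")

    def test_death_before_index_is_contract_violation(self, config):
        patient = make_patient(death_date="2017-06-01")
        with pytest.raises(ValueError):
            compute_followup_end("case", INDEX, [], patient, "DM", config)


class TestWashout:
    def test_event_in_washout_blocks_that_outcome(self, config):
        events = [make_event("2017-10-01", "GERD")]
        assert not washout_eligibility("GERD", INDEX, events, config)

    def test_event_before_washout_does_not_block(self, config):
        events = [make_event("2016-12-01", "GERD")]  # 13 months pre-index
        assert washout_eligibility("GERD", INDEX, events, config)

    def test_washout_is_outcome_specific(self, config):
        events = [make_event("2017-10-01", "GERD")]
        assert not washout_eligibility("GERD", INDEX, events, config)
        assert washout_eligibility("ILD", INDEX, events, config)

    def test_death_has_no_washout(self, config):
        assert washout_eligibility("all_cause_death", INDEX, [], config)


class TestObserveEvents:
    def test_censored_subject_accrues_full_time(self, config):
        obs = {
            o["outcome"]: o
            for o in observe_events(INDEX, days(730), [], pd.NaT, config)
        }
        gerd = obs["GERD"]
        assert gerd["eligible"] and pd.isna(gerd["event_date"])
        assert gerd["time_at_risk_days"] == 730

    def test_first_occurrence_stops_the_clock(self, config):
        events = [
            make_event(days(10), "GERD"), make_event(days(200), "GERD"),
        ]
        obs = {
            o["outcome"]: o
            for o in observe_events(INDEX, days(730), events, pd.NaT, config)
        }
        assert obs["GERD"]["event_date"] == days(10)
        assert obs["GERD"]["time_at_risk_days"] == 10

    def test_death_is_event_and_censor(self, config):
        death = days(365)
        obs = {
            o["outcome"]: o
            for o in observe_events(INDEX, death, [], death, config)
        }
        assert obs["all_cause_death"]["event_date"] == death
        assert obs["all_cause_death"]["time_at_risk_days"] == 365
        assert obs["GERD"]["time_at_risk_days"] == 365
        assert pd.isna(obs["GERD"]["event_date"])

    def test_event_on_index_date_is_incident_at_zero_days(self, config):
        events = [make_event(INDEX, "GERD")]
        obs = {
            o["outcome"]: o
            for o in observe_events(INDEX, days(100), events, pd.NaT, config)
        }
        assert obs["GERD"]["event_date"] == INDEX
        assert obs["GERD"]["time_at_risk_days"] == 0

    def test_ineligible_outcome_gets_zero_risk_time(self, config):
        events = [make_event("2017-10-01", "GERD")]
        obs = {
            o["outcome"]: o
            for o in observe_events(INDEX, days(500), events, pd.NaT, config)
        }
        assert not obs["GERD"]["eligible"]
        assert obs["GERD"]["time_at_risk_days"] == 0
        assert obs["ILD"]["time_at_risk_days"] == 500

    def test_washout_toggle_is_orthogonal_across_outcomes(self, config):
        base_events = [make_event(days(40), "ILD")]
        with_washout = base_events + [make_event("2017-09-01", "GERD")]
        before = observe_events(INDEX, days(600), base_events, pd.NaT, config)
        after = observe_events(INDEX, days(600), with_washout, pd.NaT, config)
        for b, a in zip(before, after):
            if b["outcome"] == "GERD":
                assert b["eligible"] and not a["eligible"]
            else:
                assert b == a

    def test_risk_time_never_exceeds_followup(self, config):
        events = [make_event(days(5), "GERD"), make_event(days(90), "ILD")]
        for obs in observe_events(INDEX, days(90), events, pd.NaT, config):
            assert obs["time_at_risk_days"] <= 90
            if pd.notna(obs["event_date"]):
                assert obs["event_date"] <= days(90)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def daily_scan_oracle(role, index_day, study_end_day, death_day, act_end_day,
                      other_inpatient, other_outpatient, any_dx):
    """Walk forward one day at a time applying the censoring rules literally.

    Day numbers are offsets from an arbitrary epoch; event-day collections
    may contain duplicates (two outpatient diagnoses on one day both count).
    """
    outpatient_seen = 0
    day = index_day
    while True:
        if death_day is not None and day == death_day:
            return day, "death"
        if day == act_end_day:
            return day, "end_of_activity"
        if role == "case":
            if day in other_inpatient:
                return day, "subtype_switch"
            outpatient_seen += sum(1 for d in other_outpatient if d == day)
            if outpatient_seen >= 2:
                return day, "subtype_switch"
        else:
            if day in any_dx:
                return day, "control_iim_dx"
        if day == study_end_day:
            return day, "study_end"
        day += 1


def random_subject(rng, config, role):
    epoch = config.study_start
    index_day = int(rng.integers(200, 1500))
    index = epoch + pd.Timedelta(days=index_day)
    act_end_day = index_day + int(rng.integers(0, 1400))
    death_day = None
    if rng.random() < 0.35:
        death_day = index_day + int(rng.integers(0, 1400))
        act_end_day = max(act_end_day, death_day)
    subtype = "DM" if rng.random() < 0.5 else "PM"
    other = "PM" if subtype == "DM" else "DM"
    events = []
    other_in, other_out, any_dx = [], [], []
    for _ in range(int(rng.integers(0, 5))):
        d = index_day + int(rng.integers(-200, 1200))
        if d < index_day:
            continue  # pre-index diagnoses exercise the >= index filter below
        setting = "inpatient" if rng.random() < 0.4 else "outpatient"
        cat = other if role == "case" else ("DM" if rng.random() < 0.5 else "PM")
        events.append(
            make_event(epoch + pd.Timedelta(days=d), cat, setting)
        )
        if role == "case":
            (other_in if setting == "inpatient" else other_out).append(d)
        else:
            any_dx.append(d)
    if role == "case":
        # same-subtype diagnoses must never censor
        for _ in range(int(rng.integers(0, 3))):
            d = index_day + int(rng.integers(0, 1200))
            events.append(
                make_event(epoch + pd.Timedelta(days=d), subtype, "outpatient")
            )
    events.sort(key=lambda e: e.date)
    patient = make_patient(
        activity_start="2014-01-01",
        activity_end=(epoch + pd.Timedelta(days=act_end_day)),
        death_date=(
            epoch + pd.Timedelta(days=death_day)
            if death_day is not None else None
        ),
    )
    return (patient, events, index, subtype, index_day, death_day,
            act_end_day, other_in, other_out, any_dx)


def test_followup_end_matches_daily_scan_on_random_subjects(config):
    rng = np.random.default_rng(2024)
    study_end_day = (config.study_end - config.study_start).days
    for trial in range(300):
        role = "case" if trial % 2 == 0 else "control"
        (patient, events, index, subtype, index_day, death_day, act_end_day,
         other_in, other_out, any_dx) = random_subject(rng, config, role)
        fu_end, reason = compute_followup_end(
            role, index, events, patient, subtype, config
        )
        want_day, want_reason = daily_scan_oracle(
            role, index_day, study_end_day, death_day, act_end_day,
            set(other_in), other_out, set(any_dx),
        )
        got_day = (fu_end - config.study_start).days
        assert (got_day, reason) == (want_day, want_reason)
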