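"""Follow-up intervals, per-outcome washout eligibility, first-event
observation, and person-time at risk.

Follow-up runs from the index date to the earliest of: death, end of
database activity, a subtype switch (for cases: one inpatient or two
outpatient post-index diagnoses of the *other* subtype; for controls: any
DM/PM diagnosis), or the end of the study period.  Same-day ties resolve by
the fixed priority death > end_of_activity > switch/control diagnosis >
study_end.

Each of the 13 outcomes is followed independently: a subject with an
occurrence of an outcome inside the 12-month pre-index washout is not
followed for that outcome (and contributes no person-time to it) but remains
at risk for every other outcome.  Follow-up for an outcome ends at its first
post-index occurrence; all-cause death has no washout and is sourced from
the patient table's death date rather than coded events.  Person-time is
measured in days and converted to person-years as days/365.25.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from ._dates import DAYS_PER_YEAR, add_months
from .cohorts import group_events
from .labels import ALL_CAUSE_DEATH, OUTCOMES, SUBTYPES, control_group, other_subtype
from .tables_io import StudyConfig

FOLLOWUP_COLUMNS = [
    "subject_id", "role", "group", "index_date", "fu_end", "censor_reason",
]
OBSERVATION_COLUMNS = [
    "subject_id", "role", "group", "outcome", "eligible",
    "index_date", "fu_end", "event_date", "time_at_risk_days",
]

#: same-day tie priority, smaller wins
_REASON_PRIORITY = {
    "death": 0, "end_of_activity": 1,
    "subtype_switch": 2, "control_iim_dx": 2,
    "study_end": 3,
}


def compute_followup_end(
    role: str,
    index_date: pd.Timestamp,
    events: Iterable,
    patient,
    cohort_subtype: Optional[str],
    config: StudyConfig,
) -> tuple[pd.Timestamp, str]:
    """Earliest censoring date and its reason for one subject.

    ``events`` is the subject's own date-sorted event list.  ``cohort_subtype``
    is the case's assigned subtype (ignored for controls).  Death before the
    index date violates the cohort contract and raises.
    """
    death = patient.death_date if pd.notna(patient.death_date) else None
    if death is not None and death < index_date:
        raise ValueError(
            f"subject {patient.patient_id!r}: death precedes index date"
        )
    candidates = [(config.study_end, "study_end"),
                  (patient.activity_end, "end_of_activity")]
    if death is not None:
        candidates.append((death, "death"))

    if role == "case":
        other = other_subtype(cohort_subtype)
        first_inpatient = None
        outpatient_dates = []
        for ev in events:
            if (ev.event_class == "diagnosis" and ev.category == other
                    and ev.date >= index_date):
                if ev.setting == "inpatient":
                    if first_inpatient is None:
                        first_inpatient = ev.date
                else:
                    outpatient_dates.append(ev.date)
        switch_dates = []
        if first_inpatient is not None:
            switch_dates.append(first_inpatient)
        if len(outpatient_dates) >= 2:
            switch_dates.append(outpatient_dates[1])
        if switch_dates:
            candidates.append((min(switch_dates), "subtype_switch"))
    else:
        for ev in events:
            if (ev.event_class == "diagnosis" and ev.category in SUBTYPES
                    and ev.date >= index_date):
                candidates.append((ev.date, "control_iim_dx"))
                break

    return min(candidates, key=lambda c: (c[0], _REASON_PRIORITY[c[1]]))


def washout_eligibility(
    outcome: str,
    index_date: pd.Timestamp,
    events: Iterable,
    config: StudyConfig,
) -> bool:
    """False iff the outcome occurred in ``[index - washout_months, index)``.

    All-cause death has no washout and is always eligible.
    """
    if outcome == ALL_CAUSE_DEATH:
        return True
    washout_start = add_months(index_date, -config.washout_months)
    return _eligible(outcome, washout_start, index_date, events)


def _eligible(outcome, washout_start, index_date, events) -> bool:
    for ev in events:
        if ev.category == outcome and washout_start <= ev.date < index_date:
            return False
    return True


def observe_events(
    index_date: pd.Timestamp,
    fu_end: pd.Timestamp,
    events: Iterable,
    death_date,
    config: StudyConfig,
) -> list[dict]:
    """One observation per outcome: eligibility, first event, risk time.

    An eligible subject's event date is the earliest matching occurrence in
    the closed interval ``[index_date, fu_end]`` (an event on the index date
    itself is incident, at 0 days at risk); ineligible outcomes contribute no
    person-time.
    """
    observations = []
    washout_start = add_months(index_date, -config.washout_months)
    for outcome in OUTCOMES:
        eligible = (
            outcome == ALL_CAUSE_DEATH
            or _eligible(outcome, washout_start, index_date, events)
        )
        if not eligible:
            observations.append(
                {"outcome": outcome, "eligible": False,
                 "event_date": pd.NaT, "time_at_risk_days": 0}
            )
            continue
        event_date = pd.NaT
        if outcome == ALL_CAUSE_DEATH:
            if pd.notna(death_date) and index_date <= death_date <= fu_end:
                event_date = death_date
        else:
            for ev in events:
                if ev.category == outcome and index_date <= ev.date <= fu_end:
                    event_date = ev.date
                    break
        end = event_date if pd.notna(event_date) else fu_end
        observations.append(
            {"outcome": outcome, "eligible": True, "event_date": event_date,
             "time_at_risk_days": int((end - index_date).days)}
        )
    return observations


def compute_observations(
    assignments: pd.DataFrame,
    pairs: pd.DataFrame,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Follow every case and matched control; one observation row per
    subject x outcome.

    Returns ``(followups, observations)``.  Controls carry the group label
    ``MC_<cohort>`` of their case's cohort and start follow-up on the shared
    index date.
    """
    grouped = group_events(events)
    patient_rows = {p.patient_id: p for p in patients.itertuples(index=False)}
    cohort_of_case = dict(zip(assignments["patient_id"], assignments["cohort"]))

    subjects = [
        (a.patient_id, "case", a.cohort, a.index_date, a.subtype)
        for a in assignments.itertuples(index=False)
    ]
    subjects += [
        (p.control_id, "control", control_group(cohort_of_case[p.case_id]),
         p.index_date, None)
        for p in pairs.itertuples(index=False)
    ]

    fu_rows, obs_rows = [], []
    for subject_id, role, group, index_date, subtype in subjects:
        patient = patient_rows[subject_id]
        evs = grouped.get(subject_id, [])
        fu_end, reason = compute_followup_end(
            role, index_date, evs, patient, subtype, config
        )
        fu_rows.append((subject_id, role, group, index_date, fu_end, reason))
        for obs in observe_events(
            index_date, fu_end, evs, patient.death_date, config
        ):
            obs_rows.append(
                (subject_id, role, group, obs["outcome"], obs["eligible"],
                 index_date, fu_end, obs["event_date"],
                 obs["time_at_risk_days"])
            )

    followups = pd.DataFrame(fu_rows, columns=FOLLOWUP_COLUMNS)
    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    return followups, observations


def person_years(days) -> float:
    return float(days) / DAYS_PER_YEAR
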