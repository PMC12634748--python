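"""Incident-case identification via the weighted exposure-assessment-window
(EAW) algorithm.

A patient's first DM/PM diagnosis inside the study period opens a 6-month
EAW (half-open: ``[first_dx, first_dx + eaw_months)``).  Within the window
each inpatient DM/PM diagnosis contributes 2 counts and each outpatient
diagnosis 1 count to its subtype; the subtype with the higher tally wins,
ties go to the subtype of the last diagnosis in the window, and a patient
whose window contains only outpatient diagnoses needs at least 2 outpatient
diagnoses of the winning subtype.  The index date — the start of follow-up —
is the day after the window's last included day, i.e. ``first_dx +
eaw_months``.  Patients aged 12 to <18 at index form the juvenile (JDM/JPM)
cohorts; younger patients are excluded.

Eligibility screens run in a fixed order so every excluded patient carries
exactly one primary reason (reproducible attrition tables):
``not_in_idn`` -> ``insufficient_pre_activity`` ->
``insufficient_post_activity`` -> ``prior_iim_dx`` ->
``outpatient_rule_failed``/``no_subtype`` -> ``under_min_age``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._dates import add_months, completed_years
from .labels import JUVENILE, SUBTYPES
from .tables_io import StudyConfig

EXCLUSION_REASONS = (
    "no_iim_dx",
    "not_in_idn",
    "insufficient_pre_activity",
    "insufficient_post_activity",
    "prior_iim_dx",
    "outpatient_rule_failed",
    "under_min_age",
    "no_subtype",
)

ASSIGNMENT_COLUMNS = [
    "patient_id", "first_iim_date", "eaw_start", "eaw_end", "index_date",
    "subtype", "cohort", "age_at_index", "dm_count", "pm_count",
]


@dataclass
class EawScore:
    """Weighted diagnosis tallies over one patient's EAW."""

    dm_count: int = 0
    pm_count: int = 0
    dm_outpatient_n: int = 0
    pm_outpatient_n: int = 0
    has_any_inpatient: bool = False
    last_dx_subtype: Optional[str] = None
    last_dx_date: Optional[pd.Timestamp] = None


def group_events(events: pd.DataFrame) -> dict[str, list]:
    """Per-patient event lists, preserving the (date, input-row) sort order."""
    grouped: dict[str, list] = {}
    for row in events.itertuples(index=False):
        grouped.setdefault(row.patient_id, []).append(row)
    return grouped


def _is_subtype_dx(ev) -> bool:
    return ev.event_class == "diagnosis" and ev.category in SUBTYPES


def first_iim_diagnosis(events: Iterable, config: StudyConfig):
    """Earliest DM/PM diagnosis dated within [study_start, study_end].

    ``events`` must be date-sorted (the :mod:`tables_io` sort contract).
    Returns the date, or None when the patient has no in-period diagnosis.
    """
    for ev in events:
        if _is_subtype_dx(ev) and config.study_start <= ev.date <= config.study_end:
            return ev.date
    return None


def check_eligibility(patient, events: Iterable, first_dx, config: StudyConfig):
    """First failing screen, or None when the patient is eligible.

    Requires care through an integrated delivery network, continuous database
    activity spanning ``pre_activity_months`` before and
    ``post_activity_months`` after the first in-period diagnosis, and no
    DM/PM diagnosis at any earlier point in the database.
    """
    if not patient.in_idn:
        return "not_in_idn"
    if patient.activity_start > add_months(first_dx, -config.pre_activity_months):
        return "insufficient_pre_activity"
    if patient.activity_end < add_months(first_dx, config.post_activity_months):
        return "insufficient_post_activity"
    for ev in events:
        if _is_subtype_dx(ev) and ev.date < first_dx:
            return "prior_iim_dx"
    return None


def score_eaw(events: Iterable, eaw_start, eaw_end, config: StudyConfig) -> EawScore:
    """Tally weighted DM/PM diagnoses over the half-open window
    ``[eaw_start, eaw_end)``.

    The window-opening diagnosis itself is included.  ``last_dx_subtype`` is
    the subtype of the latest in-window diagnosis; same-day ties go to the
    later input row (events arrive in (date, row) order, so the last one
    seen wins).
    """
    score = EawScore()
    for ev in events:
        if not _is_subtype_dx(ev) or not (eaw_start <= ev.date < eaw_end):
            continue
        weight = (
            config.inpatient_weight if ev.setting == "inpatient"
            else config.outpatient_weight
        )
        if ev.category == "DM":
            score.dm_count += weight
            if ev.setting == "outpatient":
                score.dm_outpatient_n += 1
        else:
            score.pm_count += weight
            if ev.setting == "outpatient":
                score.pm_outpatient_n += 1
        if ev.setting == "inpatient":
            score.has_any_inpatient = True
        score.last_dx_subtype = ev.category
        score.last_dx_date = ev.date
    return score


def assign_subtype(score: EawScore, config: StudyConfig) -> Optional[str]:
    """Subtype with the highest weighted count; ties go to the last
    diagnosis; outpatient-only patients need >= ``min_outpatient_only``
    outpatient diagnoses of the winning subtype.  None when unassignable.
    """
    if score.dm_count == 0 and score.pm_count == 0:
        return None
    if score.dm_count > score.pm_count:
        provisional = "DM"
    elif score.pm_count > score.dm_count:
        provisional = "PM"
    else:
        provisional = score.last_dx_subtype
    if not score.has_any_inpatient:
        out_n = (
            score.dm_outpatient_n if provisional == "DM"
            else score.pm_outpatient_n
        )
        if out_n < config.min_outpatient_only:
            return None
    return provisional


def build_cohorts(
    patients: pd.DataFrame, events: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full algorithm over a population.

    Returns ``(assignments, exclusions)``.  Every patient with at least one
    in-period DM/PM diagnosis appears in exactly one of the two frames;
    patients with none are silently outside the study.
    """
    grouped = group_events(events)
    assignments, exclusions = [], []
    for patient in patients.itertuples(index=False):
        evs = grouped.get(patient.patient_id, [])
        first_dx = first_iim_diagnosis(evs, config)
        if first_dx is None:
            continue
        reason = check_eligibility(patient, evs, first_dx, config)
        if reason is None:
            eaw_start = first_dx
            eaw_end = add_months(first_dx, config.eaw_months)
            index_date = eaw_end  # day after the window's last included day
            score = score_eaw(evs, eaw_start, eaw_end, config)
            subtype = assign_subtype(score, config)
            if subtype is None:
                reason = (
                    "no_subtype"
                    if score.dm_count == 0 and score.pm_count == 0
                    else "outpatient_rule_failed"
                )
            else:
                age = completed_years(patient.birth_date, index_date)
                if age < config.min_age_years:
                    reason = "under_min_age"
                else:
                    cohort = (
                        subtype if age >= config.adult_age_years
                        else JUVENILE[subtype]
                    )
                    assignments.append(
                        (patient.patient_id, first_dx, eaw_start, eaw_end,
                         index_date, subtype, cohort, age,
                         score.dm_count, score.pm_count)
                    )
                    continue
        exclusions.append((patient.patient_id, reason))

    assignments_df = pd.DataFrame(assignments, columns=ASSIGNMENT_COLUMNS)
    exclusions_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return assignments_df, exclusions_df
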