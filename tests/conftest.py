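"""Shared fixtures and lightweight row builders for the test suite."""

from collections import namedtuple

import pandas as pd
import pytest

from iimcohort import StudyConfig
from iimcohort.tables_io import EVENT_COLUMNS, PATIENT_COLUMNS

Patient = namedtuple(
    "Patient",
    ["patient_id", "birth_date", "sex", "activity_start", "activity_end",
     "death_date", "in_idn"],
)
Event = namedtuple(
    "Event", ["patient_id", "date", "category", "setting", "event_class"]
)


def make_patient(
    patient_id="P1",
    birth_date="1970-01-01",
    sex="female",
    activity_start="2014-01-01",
    activity_end="2022-01-01",
    death_date=None,
    in_idn=True,
) -> Patient:
    return Patient(
        patient_id,
        pd.Timestamp(birth_date),
        sex,
        pd.Timestamp(activity_start),
        pd.Timestamp(activity_end),
        pd.Timestamp(death_date) if death_date else pd.NaT,
        in_idn,
    )


def make_event(
    date, category, setting="outpatient", event_class="diagnosis",
    patient_id="P1",
) -> Event:
    return Event(patient_id, pd.Timestamp(date), category, setting, event_class)


def patients_frame(patients) -> pd.DataFrame:
    return pd.DataFrame(patients, columns=PATIENT_COLUMNS)


def events_frame(events) -> pd.DataFrame:
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if df.empty:
        df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture
def config() -> StudyConfig:
    return StudyConfig()
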