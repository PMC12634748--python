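"""Read, validate, and write the pipeline's tabular inputs and the run
configuration.

File formats (all delimited text, ISO-8601 dates, no times):

* ``patients.csv`` — ``patient_id,birth_date,sex,activity_start,activity_end,
  death_date,in_idn`` with ``death_date`` empty when absent and ``in_idn`` in
  {0,1}.  One row per person; activity is a single continuous interval.
* ``events.csv`` — ``patient_id,date,category,setting,event_class``.
  ``setting`` must be inpatient/outpatient for diagnoses and is ``na``
  otherwise.  ``category`` is a pre-mapped label (subtype, outcome,
  comorbidity, or medication class); raw code-to-category mapping is the
  caller's job (see :func:`apply_code_map`).
* ``config.yaml`` — keys matching :class:`StudyConfig` fields.

Validation is strict: schema problems name the offending column, row
problems carry the 1-based file line number, and integrity problems (interval
order, duplicate ids) name the patient.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._dates import to_date

log = logging.getLogger(__name__)

SEXES = ("female", "male")
SETTINGS = ("inpatient", "outpatient", "na")
EVENT_CLASSES = ("diagnosis", "medication", "procedure")

PATIENT_COLUMNS = [
    "patient_id", "birth_date", "sex", "activity_start", "activity_end",
    "death_date", "in_idn",
]
EVENT_COLUMNS = ["patient_id", "date", "category", "setting", "event_class"]


class TableError(ValueError):
    """Base class for table/config validation failures."""


class SchemaError(TableError):
    """A required column is missing or a column holds an illegal value set."""


class RowError(TableError):
    """A single row failed to parse; carries the file line number."""


class IntegrityError(TableError):
    """A cross-field or cross-row invariant is violated."""


class ConfigError(TableError):
    """The run configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Study-level parameters.

    Defaults encode the design: a 6-month exposure assessment window (EAW)
    opened by the first in-period DM/PM diagnosis, >=6 months of database
    activity before and after that diagnosis, a 12-month pre-index washout
    per outcome, inpatient diagnoses weighted 2:1 over outpatient, and exact
    Poisson 95% intervals on rates per 100 person-years.
    """

    study_start: pd.Timestamp = pd.Timestamp("2016-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2021-03-31")
    eaw_months: int = 6
    pre_activity_months: int = 6
    post_activity_months: int = 6
    washout_months: int = 12
    baseline_months: int = 12
    med_window_months: int = 7  # EAW plus the first month post-index
    min_age_years: int = 12
    adult_age_years: int = 18
    inpatient_weight: int = 2
    outpatient_weight: int = 1
    min_outpatient_only: int = 2
    ir_scale: float = 100.0  # rates reported per this many person-years
    ci_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.study_start = to_date(self.study_start)
        self.study_end = to_date(self.study_end)
        if not self.study_start < self.study_end:
            raise ConfigError("study_start must precede study_end")
        for name in ("eaw_months", "pre_activity_months", "post_activity_months",
                     "washout_months", "baseline_months", "med_window_months",
                     "min_age_years", "adult_age_years", "inpatient_weight",
                     "outpatient_weight", "min_outpatient_only"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
            setattr(self, name, int(getattr(self, name)))
        if not 0.0 < float(self.ci_level) < 1.0:
            raise ConfigError("ci_level must be in (0, 1)")
        if float(self.ir_scale) <= 0:
            raise ConfigError("ir_scale must be positive")
        self.ci_level = float(self.ci_level)
        self.ir_scale = float(self.ir_scale)
        self.rng_seed = int(self.rng_seed)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.date().isoformat()
        d["study_end"] = self.study_end.date().isoformat()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _parse_date_column(df: pd.DataFrame, col: str, path, allow_blank=False) -> pd.Series:
    raw = df[col].str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    blank = raw == ""
    bad = parsed.isna() & ~blank
    if bad.any():
        i = int(bad.idxmax())
        raise RowError(
            f"{Path(path).name} line {i + 2}: unparseable {col} "
            f"value {raw.iloc[i]!r} (expected YYYY-MM-DD)"
        )
    if not allow_blank and blank.any():
        i = int(blank.idxmax())
        raise RowError(f"{Path(path).name} line {i + 2}: blank {col}")
    return parsed


def _check_enum(df: pd.DataFrame, col: str, allowed, path) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"{Path(path).name} line {i + 2}: {col} value "
            f"{df[col].iloc[i]!r} not in {sorted(allowed)}"
        )


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------

def read_patients(path) -> pd.DataFrame:
    """Load and validate a patient table; row order is preserved.

    Raises :class:`SchemaError` for missing columns or illegal enum values,
    :class:`RowError` for unparseable dates (with the file line number), and
    :class:`IntegrityError` for interval violations or duplicate ids.
    """
    df = _read_csv(path, PATIENT_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"].str.strip()})
    if (out["patient_id"] == "").any():
        i = int((out["patient_id"] == "").idxmax())
        raise RowError(f"{Path(path).name} line {i + 2}: empty patient_id")
    dup = out["patient_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate patient_id {out['patient_id'][dup].iloc[0]!r}"
        )
    out["birth_date"] = _parse_date_column(df, "birth_date", path)
    sex = df["sex"].str.strip().str.lower()
    df = df.assign(sex=sex)
    _check_enum(df, "sex", SEXES, path)
    out["sex"] = sex
    out["activity_start"] = _parse_date_column(df, "activity_start", path)
    out["activity_end"] = _parse_date_column(df, "activity_end", path)
    out["death_date"] = _parse_date_column(df, "death_date", path, allow_blank=True)
    idn = df["in_idn"].str.strip().str.lower()
    mapping = {"0": False, "1": True, "true": True, "false": False}
    if (~idn.isin(mapping)).any():
        i = int((~idn.isin(mapping)).idxmax())
        raise SchemaError(
            f"{Path(path).name} line {i + 2}: in_idn value {idn.iloc[i]!r} "
            "not in {0,1,true,false}"
        )
    out["in_idn"] = idn.map(mapping).astype(bool)

    bad = out["activity_start"] > out["activity_end"]
    if bad.any():
        pid = out.loc[bad, "patient_id"].iloc[0]
        raise IntegrityError(
            f"patient {pid!r}: activity_end precedes activity_start"
        )
    bad = out["death_date"].notna() & (out["death_date"] < out["activity_start"])
    if bad.any():
        pid = out.loc[bad, "patient_id"].iloc[0]
        raise IntegrityError(f"patient {pid!r}: death_date before activity_start")
    return out.reset_index(drop=True)


def write_patients(patients: pd.DataFrame, path) -> None:
    out = patients.copy()
    for col in ("birth_date", "activity_start", "activity_end", "death_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out["in_idn"] = out["in_idn"].astype(int)
    out[PATIENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def read_events(path) -> pd.DataFrame:
    """Load and validate an event table.

    Input rows may be unsorted; the returned frame is sorted by
    ``(patient_id, date)`` with ties broken by input row order (stable sort),
    which is the ordering the downstream same-date tiebreaks rely on.
    """
    df = _read_csv(path, EVENT_COLUMNS)
    out = pd.DataFrame({"patient_id": df["patient_id"].str.strip()})
    out["date"] = _parse_date_column(df, "date", path)
    cat = df["category"].str.strip()
    if (cat == "").any():
        i = int((cat == "").idxmax())
        raise RowError(f"{Path(path).name} line {i + 2}: empty category")
    out["category"] = cat
    setting = (
        df["setting"].str.strip().str.lower().replace({"n/a": "na", "": "na"})
    )
    df = df.assign(setting=setting)
    _check_enum(df, "setting", SETTINGS, path)
    out["setting"] = setting
    klass = df["event_class"].str.strip().str.lower()
    df = df.assign(event_class=klass)
    _check_enum(df, "event_class", EVENT_CLASSES, path)
    out["event_class"] = klass
    bad = (out["event_class"] == "diagnosis") & (out["setting"] == "na")
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"{Path(path).name} line {i + 2}: diagnosis rows need an "
            "inpatient/outpatient setting"
        )
    return sort_events(out)


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (patient_id, date); same-day ties keep input order."""
    return events.sort_values(
        ["patient_id", "date"], kind="mergesort"
    ).reset_index(drop=True)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def apply_code_map(
    raw_events: pd.DataFrame,
    code_map: Mapping[str, str],
    on_unmapped: str = "drop",
) -> tuple[pd.DataFrame, int]:
    """Translate raw coded events (column ``code``) into category labels.

    Many codes may map to one category.  Unmapped codes are dropped with the
    count logged (``on_unmapped="drop"``, the default) or raise
    (``on_unmapped="error"``).  Returns ``(events, n_dropped)``.
    """
    if "code" not in raw_events.columns:
        raise SchemaError("raw events: missing column(s) ['code']")
    mapped = raw_events["code"].map(dict(code_map))
    unmapped = mapped.isna()
    n_dropped = int(unmapped.sum())
    if n_dropped and on_unmapped == "error":
        raise SchemaError(
            f"{n_dropped} events carry codes absent from the code map "
            f"(first: {raw_events.loc[unmapped, 'code'].iloc[0]!r})"
        )
    if n_dropped:
        log.info("apply_code_map: dropped %d unmapped events", n_dropped)
    out = raw_events[~unmapped].copy()
    out["category"] = mapped[~unmapped]
    out = out.drop(columns=["code"])
    cols = [c for c in EVENT_COLUMNS if c in out.columns]
    return out[cols + [c for c in out.columns if c not in cols]], n_dropped


def read_code_map(path) -> dict[str, str]:
    df = _read_csv(path, ["code", "category"])
    return dict(zip(df["code"].str.strip(), df["category"].str.strip()))
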