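"""Synthetic longitudinal claims-style population with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external data:

* incident cases with a true subtype (DM or PM), a first diagnosis date
  placed so that window and activity margins are satisfiable, and a mixed
  diagnosis history inside the exposure assessment window — each subsequent
  diagnosis is inpatient with probability ``inpatient_prob`` and coded as
  the *opposite* subtype with probability ``misclass_prob`` (symmetric
  coding noise);
* a disease-free background pool for control matching, constructed so each
  case has compatible (same birth year and sex, database-active) candidates;
* outcome events with group-specific constant hazards: cases draw an
  exponential first-arrival clock from their index date, background patients
  carry a full homogeneous Poisson process over their activity interval —
  memoryless, so the post-index rate is the nominal control rate no matter
  which case's index date their follow-up ends up anchored to;
* washout "prior" events for cases, deaths and database dropout as competing
  exponential clocks from index.

Everything is driven by one :class:`numpy.random.Generator`; identical
(scenario, config, seed) gives byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._dates import DAYS_PER_YEAR, add_months, completed_years
from .labels import ALL_CAUSE_DEATH, SUBTYPES
from .tables_io import ConfigError, StudyConfig

TRUTH_PATIENT_COLUMNS = [
    "patient_id", "true_subtype", "true_index_date", "true_age_band",
    "true_prior_iim",
]
TRUTH_OUTCOME_COLUMNS = [
    "patient_id", "outcome", "true_event_date", "true_prior_event",
]

#: latent event dates beyond this offset are recorded as absent
_MAX_LATENT_DAYS = 80 * 365


@dataclass
class SimulationScenario:
    """Parameters of one synthetic population.

    Rates are per person-year; fractions in [0, 1].  ``outcome_hazards``
    maps outcome label -> ``{"case_rate": ..., "control_rate": ...}``.
    ``prior_event_prob`` (outcome -> fraction) injects washout-period events
    into case histories.  The exclusion-rule exercisers
    (``prior_iim_prob``, ``under_age_fraction``, ``non_idn_prob``) default
    to 0 so the base population is fully eligible by construction.
    """

    n_cases: int = 1000
    n_background: int = 4000
    true_subtype_split: float = 0.5   # fraction of cases truly DM
    juvenile_fraction: float = 0.02   # index age in [12, 18)
    n_eaw_dx: int = 3                 # diagnoses after the window-opener
    inpatient_prob: float = 0.2
    misclass_prob: float = 0.0
    outcome_hazards: dict = field(default_factory=dict)
    prior_event_prob: dict = field(default_factory=dict)
    death_rate_case: float = 0.0
    death_rate_control: float = 0.0
    dropout_rate: float = 0.0
    female_fraction: float = 0.7
    prior_iim_prob: float = 0.0
    under_age_fraction: float = 0.0
    non_idn_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_background < 0:
            raise ConfigError("population sizes must be >= 0")
        if self.n_eaw_dx < 1:
            raise ConfigError("n_eaw_dx must be >= 1")
        for name in ("true_subtype_split", "juvenile_fraction",
                     "inpatient_prob", "misclass_prob", "female_fraction",
                     "prior_iim_prob", "under_age_fraction", "non_idn_prob"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("death_rate_case", "death_rate_control", "dropout_rate"):
            if float(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for label, rates in self.outcome_hazards.items():
            if rates["case_rate"] < 0 or rates["control_rate"] < 0:
                raise ConfigError(f"negative hazard for {label}")
        for label, p in self.prior_event_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prior_event_prob[{label}] must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


@dataclass
class GroundTruth:
    """Latent state of a simulated population.

    ``patients``: per patient — true subtype ("DM"/"PM"/"none"), true index
    date (NaT for background), age band at index, and whether a pre-study
    IIM diagnosis was injected.  ``outcomes``: per (patient, outcome) — the
    latent first event date on/after the (potential) index and whether an
    event fell in the washout window.
    """

    patients: pd.DataFrame
    outcomes: pd.DataFrame


def default_scenario(
    n_cases: int = 2000, n_background: int = 6000, seed: int = 0
) -> SimulationScenario:
    """Illustrative default scenario for an adult-skewed DM/PM population.

    Outcome hazards are set to magnitudes typical of extra-muscular
    manifestation rates reported for US adult dermatomyositis populations
    (order 0.01-0.13 events per person-year, cases above controls), e.g.
    GERD at 0.103/PY in cases versus 0.064/PY in controls.  Washout prior
    probabilities mirror typical 12-month baseline comorbidity prevalences.
    These are plausibility anchors for simulation, not reproduction targets.
    """
    hazards = {
        "ILD": (0.028, 0.005),
        "ILD_requiring_oxygen": (0.008, 0.001),
        "heart_failure": (0.028, 0.016),
        "cardiomyopathy": (0.012, 0.007),
        "cardiac_dysrhythmia": (0.057, 0.037),
        "ischemic_heart_disease": (0.040, 0.023),
        "dysphagia": (0.053, 0.020),
        "esophageal_dysmotility": (0.007, 0.001),
        "GERD": (0.103, 0.064),
        "peptic_ulcer": (0.014, 0.006),
        "malignancy_excl_NMSC": (0.025, 0.017),
        "malignancy_main6": (0.017, 0.011),
    }
    priors = {
        "ILD": 0.16, "ILD_requiring_oxygen": 0.035, "heart_failure": 0.105,
        "cardiomyopathy": 0.045, "cardiac_dysrhythmia": 0.17,
        "ischemic_heart_disease": 0.16, "dysphagia": 0.20,
        "esophageal_dysmotility": 0.022, "GERD": 0.31, "peptic_ulcer": 0.035,
        "malignancy_excl_NMSC": 0.18, "malignancy_main6": 0.08,
    }
    return SimulationScenario(
        n_cases=n_cases,
        n_background=n_background,
        true_subtype_split=0.48,
        juvenile_fraction=0.02,
        n_eaw_dx=3,
        inpatient_prob=0.2,
        misclass_prob=0.05,
        outcome_hazards={
            k: {"case_rate": c, "control_rate": m} for k, (c, m) in hazards.items()
        },
        prior_event_prob=priors,
        death_rate_case=0.022,
        death_rate_control=0.008,
        dropout_rate=0.15,
        seed=seed,
    )


def _exp_years(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Exponential first-arrival times in years; +inf when the rate is 0."""
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, n)


def _competing_end(
    rng: np.random.Generator,
    anchor: pd.DatetimeIndex,
    death_rate: float,
    dropout_rate: float,
    config: StudyConfig,
) -> tuple[pd.DatetimeIndex, pd.DatetimeIndex]:
    """Competing death/dropout clocks from ``anchor``.

    Returns (activity_end, death_date); death_date is NaT where dropout (or
    the administrative horizon, one year past study end) comes first.
    """
    n = len(anchor)
    t_death = _exp_years(rng, death_rate, n)
    t_drop = _exp_years(rng, dropout_rate, n)
    t_end = np.minimum(t_death, t_drop)
    cap_days = (config.study_end - anchor).days + 366
    off_days = np.minimum(
        np.where(np.isfinite(t_end), np.ceil(t_end * DAYS_PER_YEAR), np.inf),
        cap_days,
    ).astype(int)
    activity_end = anchor + pd.to_timedelta(off_days, unit="D")
    died = (t_death < t_drop) & (np.ceil(t_death * DAYS_PER_YEAR) <= cap_days)
    death_date = pd.DatetimeIndex(
        np.where(died, activity_end.values, np.datetime64("NaT"))
    )
    return activity_end, death_date


def _empty_outputs() -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    from .tables_io import EVENT_COLUMNS, PATIENT_COLUMNS

    patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    for c in ("birth_date", "activity_start", "activity_end", "death_date"):
        patients[c] = pd.to_datetime(patients[c])
    events = pd.DataFrame(columns=EVENT_COLUMNS)
    events["date"] = pd.to_datetime(events["date"])
    truth = GroundTruth(
        patients=pd.DataFrame(columns=TRUTH_PATIENT_COLUMNS),
        outcomes=pd.DataFrame(columns=TRUTH_OUTCOME_COLUMNS),
    )
    return patients, events, truth


def simulate_population(
    scenario: SimulationScenario, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (patients, events, ground truth) for one scenario.

    Cases are eligible and correctly classifiable by construction when the
    noise knobs (``misclass_prob``, ``prior_iim_prob``, ``non_idn_prob``,
    ``under_age_fraction``) are zero.  Raises :class:`ConfigError` when the
    study period is too short for the window plus activity margins.
    """
    last_first_dx = add_months(
        config.study_end, -(config.eaw_months + config.post_activity_months)
    )
    if last_first_dx < config.study_start:
        raise ConfigError(
            "study period too short for the EAW plus post-index activity margin"
        )
    if scenario.n_cases == 0 and scenario.n_background == 0:
        return _empty_outputs()

    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    hazards = {
        label: (float(r["case_rate"]), float(r["control_rate"]))
        for label, r in sc.outcome_hazards.items()
    }

    patient_rows: list[tuple] = []
    truth_patients: list[tuple] = []
    event_blocks: list[pd.DataFrame] = []
    truth_outcome_blocks: list[pd.DataFrame] = []
    study_end64 = config.study_end.to_datetime64()

    def emit_block(pids, dates, categories, settings, event_class="diagnosis"):
        """Append a homogeneous batch of events (vectorized emission)."""
        size = len(pids)
        if size == 0:
            return
        event_blocks.append(
            pd.DataFrame(
                {
                    "patient_id": np.asarray(pids, dtype=object),
                    "date": pd.DatetimeIndex(dates),
                    "category": np.broadcast_to(
                        np.asarray(categories, dtype=object), (size,)
                    ).copy(),
                    "setting": np.broadcast_to(
                        np.asarray(settings, dtype=object), (size,)
                    ).copy(),
                    "event_class": event_class,
                }
            )
        )

    # ---------------- cases ----------------
    n = sc.n_cases
    case_index: pd.DatetimeIndex | None = None
    case_birth: pd.DatetimeIndex | None = None
    case_sex = np.array([], dtype=object)
    if n > 0:
        case_ids = np.array([f"C{i:06d}" for i in range(n)], dtype=object)
        true_dm = rng.random(n) < sc.true_subtype_split
        subtype = np.where(true_dm, "DM", "PM")
        juvenile = rng.random(n) < sc.juvenile_fraction
        under_age = rng.random(n) < sc.under_age_fraction

        span = (last_first_dx - config.study_start).days
        first_dx = config.study_start + pd.to_timedelta(
            rng.integers(0, span + 1, n), unit="D"
        )
        case_index = pd.DatetimeIndex(
            pd.Series(first_dx) + pd.DateOffset(months=config.eaw_months)
        )
        eaw_len = (case_index - first_dx).days.to_numpy()

        # ages drawn with a safety margin inside each band so calendar
        # completed-years never straddles a band boundary
        age = np.where(
            juvenile,
            rng.uniform(12.2, 17.8, n),
            rng.uniform(18.2, 85.0, n),
        )
        age = np.where(under_age, rng.uniform(6.0, 11.7, n), age)
        case_birth = case_index - pd.to_timedelta(
            np.round(age * DAYS_PER_YEAR).astype(int), unit="D"
        )
        case_sex = np.where(
            rng.random(n) < sc.female_fraction, "female", "male"
        ).astype(object)
        in_idn = rng.random(n) >= sc.non_idn_prob

        activity_start = pd.DatetimeIndex(
            pd.Series(first_dx) + pd.DateOffset(months=-config.pre_activity_months)
        ) - pd.to_timedelta(rng.integers(0, 366, n), unit="D")
        activity_end, death_date = _competing_end(
            rng, case_index, sc.death_rate_case, sc.dropout_rate, config
        )

        # window-opening diagnosis (always the true subtype)
        anchor_inpatient = rng.random(n) < sc.inpatient_prob
        emit_block(
            case_ids, first_dx, subtype.astype(object),
            np.where(anchor_inpatient, "inpatient", "outpatient"),
        )

        # subsequent EAW diagnoses, with symmetric misclassification
        k = sc.n_eaw_dx
        offsets = rng.integers(0, np.repeat(eaw_len, k))
        extra_inpatient = rng.random(n * k) < sc.inpatient_prob
        flipped = rng.random(n * k) < sc.misclass_prob
        rep_subtype = np.repeat(subtype, k)
        categories = np.where(
            flipped, np.where(rep_subtype == "DM", "PM", "DM"), rep_subtype
        )
        emit_block(
            np.repeat(case_ids, k),
            np.repeat(first_dx.values, k) + offsets.astype("timedelta64[D]"),
            categories.astype(object),
            np.where(extra_inpatient, "inpatient", "outpatient"),
        )

        # pre-study IIM diagnosis (exclusion-rule exerciser)
        prior_iim = rng.random(n) < sc.prior_iim_prob
        prior_off = rng.integers(1, 366, n)
        pidx = np.flatnonzero(prior_iim)
        emit_block(
            case_ids[pidx],
            config.study_start.to_datetime64()
            - prior_off[pidx].astype("timedelta64[D]"),
            subtype[pidx].astype(object), "outpatient",
        )

        # outcome clocks from index + washout priors
        for label, (case_rate, _) in hazards.items():
            t = _exp_years(rng, case_rate, n)
            off = np.where(
                np.isfinite(t), np.floor(t * DAYS_PER_YEAR), np.inf
            )
            prior_mask = rng.random(n) < sc.prior_event_prob.get(label, 0.0)
            prior_days = rng.integers(1, 361, n)

            latent = np.flatnonzero(off <= _MAX_LATENT_DAYS)
            event_dates = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
            event_dates[latent] = (
                case_index.values[latent]
                + off[latent].astype(int).astype("timedelta64[D]")
            )
            observed = latent[event_dates[latent] <= study_end64]
            emit_block(case_ids[observed], event_dates[observed], label,
                       "outpatient")
            withprior = np.flatnonzero(prior_mask)
            emit_block(
                case_ids[withprior],
                case_index.values[withprior]
                - prior_days[withprior].astype("timedelta64[D]"),
                label, "outpatient",
            )
            truth_outcome_blocks.append(
                pd.DataFrame(
                    {"patient_id": case_ids, "outcome": label,
                     "true_event_date": pd.DatetimeIndex(event_dates),
                     "true_prior_event": prior_mask}
                )
            )
        truth_outcome_blocks.append(
            pd.DataFrame(
                {"patient_id": case_ids, "outcome": ALL_CAUSE_DEATH,
                 "true_event_date": death_date, "true_prior_event": False}
            )
        )

        for i in range(n):
            age_years = completed_years(case_birth[i], case_index[i])
            if age_years < config.min_age_years:
                band = "n/a"
            elif age_years < config.adult_age_years:
                band = "juvenile"
            else:
                band = "adult"
            patient_rows.append(
                (case_ids[i], case_birth[i], case_sex[i], activity_start[i],
                 activity_end[i], death_date[i], bool(in_idn[i]))
            )
            truth_patients.append(
                (case_ids[i], subtype[i], case_index[i], band,
                 bool(prior_iim[i]))
            )

    # ---------------- background pool ----------------
    m = sc.n_background
    if m > 0:
        bg_ids = np.array([f"B{i:06d}" for i in range(m)], dtype=object)
        if n > 0:
            # template each background patient on a case so every case has
            # same-birth-year/sex candidates: ample pool by construction
            tmpl = np.arange(m) % n
            bg_years = case_birth[tmpl].year
            bg_sex = case_sex[tmpl]
            potential_index = case_index[tmpl]
        else:
            span = (last_first_dx - config.study_start).days
            pseudo_first = config.study_start + pd.to_timedelta(
                rng.integers(0, span + 1, m), unit="D"
            )
            potential_index = pd.DatetimeIndex(
                pd.Series(pseudo_first) + pd.DateOffset(months=config.eaw_months)
            )
            age = rng.uniform(18.2, 85.0, m)
            bg_years = (
                potential_index
                - pd.to_timedelta(np.round(age * DAYS_PER_YEAR).astype(int), "D")
            ).year
            bg_sex = np.where(
                rng.random(m) < sc.female_fraction, "female", "male"
            ).astype(object)
        day_of_year = rng.integers(0, 365, m)
        bg_birth = pd.DatetimeIndex(
            [pd.Timestamp(int(y), 1, 1) for y in bg_years]
        ) + pd.to_timedelta(day_of_year, unit="D")

        bg_start = config.study_start - pd.to_timedelta(
            rng.integers(0, 366, m), unit="D"
        )
        bg_end, bg_death = _competing_end(
            rng, potential_index, sc.death_rate_control, sc.dropout_rate, config
        )

        washout_start = pd.DatetimeIndex(
            pd.Series(potential_index) + pd.DateOffset(months=-config.washout_months)
        )
        obs_end = pd.DatetimeIndex(
            np.minimum(bg_end.values, config.study_end.to_datetime64())
        )
        exposure_days = (obs_end - bg_start).days.to_numpy()
        washout64 = washout_start.values
        pot64 = potential_index.values
        bg_start64 = bg_start.values
        for label, (_, control_rate) in hazards.items():
            counts = rng.poisson(control_rate * exposure_days / DAYS_PER_YEAR)
            first_after_index = np.full(
                m, np.datetime64("NaT"), dtype="datetime64[ns]"
            )
            prior_event = np.zeros(m, dtype=bool)
            pid_list: list = []
            date_list: list = []
            for i in np.flatnonzero(counts):
                offs = np.sort(rng.integers(0, exposure_days[i] + 1, counts[i]))
                dates = bg_start64[i] + offs.astype("timedelta64[D]")
                pid_list.extend([bg_ids[i]] * int(counts[i]))
                date_list.extend(dates)
                prior_event[i] = bool(
                    ((dates >= washout64[i]) & (dates < pot64[i])).any()
                )
                post = dates[dates >= pot64[i]]
                if len(post):
                    first_after_index[i] = post[0]
            emit_block(
                np.asarray(pid_list, dtype=object),
                np.asarray(date_list, dtype="datetime64[ns]"),
                label, "outpatient",
            )
            truth_outcome_blocks.append(
                pd.DataFrame(
                    {"patient_id": bg_ids, "outcome": label,
                     "true_event_date": pd.DatetimeIndex(first_after_index),
                     "true_prior_event": prior_event}
                )
            )

        truth_outcome_blocks.append(
            pd.DataFrame(
                {"patient_id": bg_ids, "outcome": ALL_CAUSE_DEATH,
                 "true_event_date": bg_death, "true_prior_event": False}
            )
        )
        for i in range(m):
            patient_rows.append(
                (bg_ids[i], bg_birth[i], bg_sex[i], bg_start[i], bg_end[i],
                 bg_death[i], True)
            )
            truth_patients.append((bg_ids[i], "none", pd.NaT, "n/a", False))

    # ---------------- assemble ----------------
    from .tables_io import EVENT_COLUMNS, PATIENT_COLUMNS, sort_events

    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    if event_blocks:
        events = pd.concat(event_blocks, ignore_index=True)[EVENT_COLUMNS]
    else:
        events = _empty_outputs()[1]
    events = sort_events(events)
    if truth_outcome_blocks:
        truth_outcomes_df = pd.concat(truth_outcome_blocks, ignore_index=True)[
            TRUTH_OUTCOME_COLUMNS
        ]
    else:
        truth_outcomes_df = pd.DataFrame(columns=TRUTH_OUTCOME_COLUMNS)
    truth = GroundTruth(
        patients=pd.DataFrame(truth_patients, columns=TRUTH_PATIENT_COLUMNS),
        outcomes=truth_outcomes_df,
    )
    return patients, events, truth
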