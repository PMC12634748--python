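"""Crude incidence rates with exact Poisson (Garwood) intervals,
progression-time summaries, and baseline characterization tables.

The crude rate for a cohort x outcome cell is ``events / person-years``
scaled to events per ``ir_scale`` (default 100) person-years.  Confidence
bounds are the exact Poisson (Garwood) interval from chi-square quantiles:

    lower = chi2.ppf(alpha/2, 2k)     / (2 T) * scale   (0 when k = 0)
    upper = chi2.ppf(1 - alpha/2, 2k + 2) / (2 T) * scale

with k events, T person-years, alpha = 1 - ci_level.  The upper bound is
positive even at zero events, which is the behaviour wanted for rare
outcomes.

Progression summaries report the arithmetic mean time from index to the
event among subjects with the event, and crude cumulative percentages of
eligible subjects with the event by 6 months, 1 year, and 2 years (subjects
censored before the horizon stay in the denominator; no survival
adjustment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import DAYS_PER_YEAR, add_months
from .labels import SUBTYPES
from .tables_io import StudyConfig

IR_COLUMNS = [
    "group", "outcome", "n_eligible", "n_events", "person_years",
    "ir", "ci_low", "ci_high",
]


class UndefinedRateError(ValueError):
    """Raised when a rate is requested over zero person-time."""


def crude_ir(
    n_events: int, person_years: float, config: StudyConfig
) -> tuple[float, float, float]:
    """Point estimate and Garwood interval, per ``config.ir_scale`` PY."""
    if person_years <= 0:
        raise UndefinedRateError("person_years must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    scale = config.ir_scale
    alpha = 1.0 - config.ci_level
    ir = scale * n_events / person_years
    if n_events == 0:
        low = 0.0
    else:
        low = stats.chi2.ppf(alpha / 2, 2 * n_events) / (2 * person_years) * scale
    high = (
        stats.chi2.ppf(1 - alpha / 2, 2 * (n_events + 1))
        / (2 * person_years) * scale
    )
    return float(ir), float(low), float(high)


def aggregate_ir(observations: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per (group, outcome): eligible n, events, person-years, rate, CI.

    Cells with zero eligible person-time are emitted with NaN rate and CI so
    the degenerate case stays visible in the output table.
    """
    rows = []
    for (group, outcome), cell in observations.groupby(
        ["group", "outcome"], sort=False
    ):
        eligible = cell[cell["eligible"]]
        n_eligible = len(eligible)
        n_events = int(eligible["event_date"].notna().sum())
        py = float(eligible["time_at_risk_days"].sum()) / DAYS_PER_YEAR
        if py > 0:
            ir, low, high = crude_ir(n_events, py, config)
        else:
            ir = low = high = np.nan
        rows.append((group, outcome, n_eligible, n_events, py, ir, low, high))
    return pd.DataFrame(rows, columns=IR_COLUMNS)


def progression_summary(
    observations: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Mean time-to-event (years) and crude cumulative percentages by
    6 months / 1 year / 2 years, per (group, outcome)."""
    obs = observations.copy()
    has_event = obs["event_date"].notna()
    obs["time_years"] = (
        (obs["event_date"] - obs["index_date"]).dt.days / DAYS_PER_YEAR
    )
    horizons = {
        "pct_at_6mo": obs["index_date"] + pd.DateOffset(months=6),
        "pct_at_1y": obs["index_date"] + pd.DateOffset(months=12),
        "pct_at_2y": obs["index_date"] + pd.DateOffset(months=24),
    }
    for col, horizon in horizons.items():
        obs[col] = has_event & (obs["event_date"] <= horizon)

    rows = []
    for (group, outcome), cell in obs.groupby(["group", "outcome"], sort=False):
        eligible = cell[cell["eligible"]]
        n_eligible = len(eligible)
        with_event = eligible[eligible["event_date"].notna()]
        mean_time = (
            float(with_event["time_years"].mean()) if len(with_event) else np.nan
        )
        pcts = [
            100.0 * eligible[col].sum() / n_eligible if n_eligible else np.nan
            for col in horizons
        ]
        rows.append(
            (group, outcome, n_eligible, len(with_event), mean_time, *pcts)
        )
    return pd.DataFrame(
        rows,
        columns=["group", "outcome", "n_eligible", "n_events",
                 "mean_time_to_event", "pct_at_6mo", "pct_at_1y", "pct_at_2y"],
    )


def baseline_tables(
    assignments: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Baseline characterization per cohort.

    Continuous rows: age at index (mean, sample SD).  Categorical rows: one
    per category label seen in the events (DM/PM excluded) — diagnoses and
    procedures are flagged over the 12-month pre-index window, medications
    over the EAW plus the first post-index month; plus sex counts.  Percent
    is out of the cohort size.
    """
    info = patients.set_index("patient_id")
    rows = []
    merged = events.merge(
        assignments[["patient_id", "cohort", "index_date", "eaw_start"]],
        on="patient_id", how="inner",
    )
    merged = merged[~merged["category"].isin(SUBTYPES)]
    baseline_start = merged["index_date"] + pd.DateOffset(
        months=-config.baseline_months
    )
    med_end = merged["eaw_start"] + pd.DateOffset(months=config.med_window_months)
    is_med = merged["event_class"] == "medication"
    in_window = np.where(
        is_med,
        (merged["date"] >= merged["eaw_start"]) & (merged["date"] < med_end),
        (merged["date"] >= baseline_start) & (merged["date"] < merged["index_date"]),
    )
    flagged = merged[in_window]

    for cohort, cell in assignments.groupby("cohort", sort=False):
        n = len(cell)
        ages = cell["age_at_index"].astype(float)
        rows.append(
            (cohort, "age_at_index", "continuous", n, np.nan,
             float(ages.mean()), float(ages.std(ddof=1)) if n > 1 else np.nan)
        )
        sexes = info.loc[cell["patient_id"], "sex"]
        for sex_label in ("female", "male"):
            count = int((sexes == sex_label).sum())
            rows.append(
                (cohort, f"sex_{sex_label}", "categorical", count,
                 100.0 * count / n, np.nan, np.nan)
            )
        cohort_flags = flagged[flagged["cohort"] == cohort]
        for label, sub in cohort_flags.groupby("category", sort=True):
            count = int(sub["patient_id"].nunique())
            rows.append(
                (cohort, label, "categorical", count, 100.0 * count / n,
                 np.nan, np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["cohort", "label", "kind", "count", "percent", "mean", "sd"],
    )


def format_ir_table(ir: pd.DataFrame, groups: list[str]) -> str:
    """Human-readable rate table, 1-decimal display, "IR (low-high)" cells."""
    outcomes = list(dict.fromkeys(ir["outcome"]))
    cell = {
        (r.group, r.outcome): (
            "--" if not np.isfinite(r.ir)
            else f"{r.ir:.1f} ({r.ci_low:.1f}-{r.ci_high:.1f})"
        )
        for r in ir.itertuples(index=False)
    }
    width = max(22, *(len(o) for o in outcomes)) + 2
    header = "Outcome".ljust(width) + "".join(g.ljust(20) for g in groups)
    lines = [header, "-" * len(header)]
    for outcome in outcomes:
        lines.append(
            outcome.ljust(width)
            + "".join(cell.get((g, outcome), "").ljust(20) for g in groups)
        )
    return "\n".join(lines)
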