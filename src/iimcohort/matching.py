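"""1:1 matched-control sampling without replacement.

Controls come from the disease-free pool (no DM/PM diagnosis at any time in
the database).  Each case is matched on birth year and sex to one control
who is database-active on the case's index date; the control inherits the
case's exact index date, so follow-up starts in the same month and year.
Cases are processed in a seeded random order and the control is drawn
uniformly from the remaining compatible candidates, so scarce controls are
not systematically awarded to early-id cases.  Cases with no compatible
candidate are reported unmatched and remain in cohort-level analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import SUBTYPES
from .tables_io import StudyConfig

PAIR_COLUMNS = ["case_id", "control_id", "birth_year", "sex", "index_date"]


def build_control_pool(patients: pd.DataFrame, events: pd.DataFrame) -> list[str]:
    """Patient ids with no DM/PM diagnosis event at any date, in input order."""
    dx = events[
        (events["event_class"] == "diagnosis")
        & events["category"].isin(SUBTYPES)
    ]
    diseased = set(dx["patient_id"])
    return [p for p in patients["patient_id"] if p not in diseased]


def match_controls(
    assignments: pd.DataFrame,
    pool: list[str],
    patients: pd.DataFrame,
    config: StudyConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Match each case to one unused control on birth year and sex.

    Returns ``(pairs, unmatched_case_ids)``; pairs are emitted in the case
    order of ``assignments`` regardless of the internal processing
    permutation, so output is deterministic given the seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    info = patients.set_index("patient_id")
    birth_year = info["birth_date"].dt.year.to_dict()
    sex = info["sex"].to_dict()
    act_start = info["activity_start"].to_dict()
    act_end = info["activity_end"].to_dict()

    strata: dict[tuple[int, str], list[str]] = {}
    for pid in pool:
        strata.setdefault((birth_year[pid], sex[pid]), []).append(pid)

    used: set[str] = set()
    pair_for_case: dict[str, str] = {}
    order = rng.permutation(len(assignments))
    rows = list(assignments.itertuples(index=False))
    for i in order:
        case = rows[i]
        key = (birth_year[case.patient_id], sex[case.patient_id])
        candidates = [
            c for c in strata.get(key, [])
            if c not in used
            and act_start[c] <= case.index_date <= act_end[c]
        ]
        if not candidates:
            continue
        chosen = candidates[int(rng.integers(len(candidates)))]
        used.add(chosen)
        pair_for_case[case.patient_id] = chosen

    pairs, unmatched = [], []
    for case in rows:
        control = pair_for_case.get(case.patient_id)
        if control is None:
            unmatched.append(case.patient_id)
        else:
            pairs.append(
                (case.patient_id, control, birth_year[case.patient_id],
                 sex[case.patient_id], case.index_date)
            )
    return pd.DataFrame(pairs, columns=PAIR_COLUMNS), unmatched
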