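"""Follow every case and matched control from index to censoring; observe
first occurrences of the 13 outcomes with per-outcome washout.

Writes follow-up intervals and subject x outcome observations to
scratch/pipeline/ and the censoring summary to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from iimcohort import StudyConfig, compute_observations, read_events, read_patients
from iimcohort._dates import DAYS_PER_YEAR

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    config = StudyConfig.from_yaml(PIPE / "config.yaml")
    patients = read_patients(PIPE / "patients.csv")
    events = read_events(PIPE / "events.csv")
    assignments = pd.read_csv(
        PIPE / "assignments.csv",
        parse_dates=["first_iim_date", "eaw_start", "eaw_end", "index_date"],
    )
    pairs = pd.read_csv(PIPE / "pairs.csv", parse_dates=["index_date"])
    followups, observations = compute_observations(
        assignments, pairs, patients, events, config
    )

    for name, frame in (("followup", followups), ("observations", observations)):
        out = frame.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
        out.to_csv(PIPE / f"{name}.csv", index=False)

    censoring = (
        followups.groupby(["role", "censor_reason"]).size().rename("n")
        .reset_index()
    )
    RESULTS.mkdir(exist_ok=True)
    censoring.to_csv(RESULTS / "censoring.csv", index=False)

    fu_years = (followups["fu_end"] - followups["index_date"]).dt.days / DAYS_PER_YEAR
    print(f"followed {len(followups)} subjects; mean follow-up "
          f"{fu_years.mean():.2f} y")
    print(censoring.to_string(index=False))
    print(f"{int(observations['event_date'].notna().sum())} outcome events "
          f"observed across {observations['outcome'].nunique()} outcomes")


if __name__ == "__main__":
    main()
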