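"""Generate the study population: incident DM/PM cases with mixed diagnosis
histories plus a disease-free background pool, with ground truth retained.

Writes the raw tables under scratch/pipeline/ (bulky, regenerated on each
run) and prints what was generated.
"""

import argparse
from pathlib import Path

from iimcohort import StudyConfig, simulate_population, write_events, write_patients
from iimcohort.synthetic import default_scenario

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "pipeline"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-cases", type=int, default=1000)
    parser.add_argument("--n-background", type=int, default=4000)
    args = parser.parse_args()

    config = StudyConfig(rng_seed=args.seed)
    scenario = default_scenario(
        n_cases=args.n_cases, n_background=args.n_background, seed=args.seed
    )
    patients, events, truth = simulate_population(scenario, config)

    OUT.mkdir(parents=True, exist_ok=True)
    write_patients(patients, OUT / "patients.csv")
    write_events(events, OUT / "events.csv")
    for name, frame in (("truth_patients", truth.patients),
                        ("truth_outcomes", truth.outcomes)):
        out = frame.copy()
        for col in out.columns:
            if "date" in col:
                out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
        out.to_csv(OUT / f"{name}.csv", index=False)
    config.to_yaml(OUT / "config.yaml")
    scenario.to_yaml(OUT / "scenario.yaml")

    n_true_dm = (truth.patients["true_subtype"] == "DM").sum()
    print(f"wrote {len(patients)} patients ({args.n_cases} cases, "
          f"{args.n_background} background) and {len(events)} events to {OUT}")
    print(f"true subtypes: {n_true_dm} DM / "
          f"{(truth.patients['true_subtype'] == 'PM').sum()} PM; "
          f"{(truth.patients['true_age_band'] == 'juvenile').sum()} juvenile cases")


if __name__ == "__main__":
    main()
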