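# iimcohort

Incident-cohort construction and crude incidence-rate estimation for
idiopathic inflammatory myopathy (IIM) — dermatomyositis (DM) and
polymyositis (PM) — in longitudinal claims-style data, with a synthetic
population generator that makes every stage testable against known ground
truth.

## The problem

DM and PM are rare autoimmune myopathies whose early coding is noisy: a
patient's first myositis diagnosis is often provisional, and the definitive
subtype emerges over subsequent encounters. Natural-history studies built on
electronic health records therefore identify incident cases with a
**weighted exposure-assessment-window (EAW) algorithm**: the first in-period
DM or PM diagnosis opens a 6-month window; inside it each inpatient DM/PM
diagnosis contributes 2 counts and each outpatient diagnosis 1 count; the
subtype with the higher tally wins, ties go to the last diagnosis in the
window, and patients with only outpatient diagnoses need ≥ 2 outpatient
diagnoses of the winning subtype. Follow-up starts on the **index date**,
the day after the window closes; patients aged 12 to < 18 at index form the
juvenile (JDM/JPM) cohorts.

Each case is matched 1:1 without replacement to a control with no DM/PM
diagnosis ever, on birth year and sex, with follow-up starting the same
date. Subjects are followed to the earliest of death, end of database
activity, a subtype switch (cases: 1 inpatient or 2 outpatient diagnoses of
the other subtype; controls: any DM/PM diagnosis), or the study end. Each of
13 outcomes (interstitial lung disease, cardiac, gastrointestinal and
malignancy outcomes, and all-cause death) is followed independently to its
first occurrence, with a 12-month pre-index washout per outcome.

The crude incidence rate for a cohort × outcome cell is

    IR = 100 · k / T      (events k, person-years T)

with the exact Poisson (Garwood) 95% interval

    lower = χ²(α/2; 2k) / 2T · 100,   upper = χ²(1−α/2; 2k+2) / 2T · 100

so zero-event cells still get a finite upper bound.

Because real claims sources are proprietary, the package ships a generator
(`iimcohort.synthetic`) that emulates their structure — subtype-labelled
incident cases with misclassification-noisy window histories, a disease-free
background pool, and outcome events with known constant hazards — so
recovery of truth by the full pipeline is a testable property.

## Worked example

```python
from iimcohort import StudyConfig, simulate_population, aggregate_ir
from iimcohort.experiments import run_pipeline
from iimcohort.synthetic import default_scenario

config = StudyConfig()                       # 2016-01-01 .. 2021-03-31
scenario = default_scenario(n_cases=1000, n_background=4000, seed=0)
patients, events, truth = simulate_population(scenario, config)
result = run_pipeline(patients, events, config, truth)
gerd = result.ir[result.ir.outcome == "GERD"]
print(gerd[["group", "n_events", "person_years", "ir", "ci_low", "ci_high"]])
```

Running the numbered drivers end to end (`python analysis/01_simulate.py
--seed 0` through `05_incidence.py`) prints, among others:

```
assigned 1000 cases: {'PM': 528, 'DM': 444, 'JPM': 18, 'JDM': 10}
subtype accuracy vs ground truth: 99.7%
matched 1000/1000 cases (0 unmatched); exact birth-year+sex match: 100.0%
followed 2000 subjects; mean follow-up 2.18 y

Outcome                 DM                  MC_DM       ...
GERD                    10.3 (7.8-13.3)     5.4 (4.0-7.2)
dysphagia               5.4 (3.8-7.6)       1.5 (0.9-2.5)
all_cause_death         3.1 (2.0-4.5)       0.7 (0.3-1.4)
```

Read: at the default scenario's GERD hazards (0.103/PY cases, 0.064/PY
controls) the pipeline estimates 10.3 (95% CI 7.8–13.3) events per 100
person-years in the DM cohort against 5.4 (4.0–7.2) in the matched
controls; 5 diagnoses per case at 5% subtype-miscoding still yield 99.7%
subtype accuracy. Final tables (rates, progression times, baseline
characteristics, attrition, censoring) land under `results/`.

## Layout

- `src/iimcohort/` — the library: `tables_io`, `synthetic`, `cohorts`,
  `matching`, `followup`, `incidence`, `experiments`, plus a thin `iimcohort`
  CLI (`validate`, `simulate`, `build-cohorts`, `match`, `follow-up`,
  `estimate`, `report`).
- `analysis/01_…05_…` — narrative drivers over the library.
- `docs/methods.md` — model, parameters, numerical conventions, limitations.
- `tests/` — unit, property, and end-to-end validation suites.
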