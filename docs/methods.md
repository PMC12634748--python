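# Methods

This note records the model the package implements, the conventions that
make it deterministic, what the synthetic generator does and does not
emulate, and the judgment calls made where the design was genuinely open.

## Cohort identification

A patient enters consideration at their earliest DM or PM diagnosis dated
inside the study period (default 2016-01-01 to 2021-03-31, both ends
included). Eligibility screens run in a fixed order, so each excluded
patient carries exactly one primary reason:

1. `not_in_idn` — care not delivered through an integrated delivery
   network (a boolean patient attribute here; network determination itself
   is out of scope).
2. `insufficient_pre_activity` / `insufficient_post_activity` — the
   activity interval must satisfy `activity_start ≤ first_dx − 6 months`
   and `activity_end ≥ first_dx + 6 months`.
3. `prior_iim_dx` — any DM/PM diagnosis at any earlier date in the
   database (incident cases only).
4. `outpatient_rule_failed` / `no_subtype` — the window algorithm below
   returned no subtype.
5. `under_min_age` — age at index under 12 completed years.

The age screen runs after subtype assignment so that algorithmic failures
are attributed to the algorithm rather than demographics; the attrition
table is unaffected for patients who fail only one screen.

**Window scoring.** The exposure assessment window is the half-open
interval `[first_dx, first_dx + 6 calendar months)`; the index date equals
its exclusive bound, honouring "the day after the window's last included
day" with a single seam convention. The window-opening diagnosis itself is
tallied — excluding it would make a single-inpatient-diagnosis patient
unassignable, which the design clearly does not intend. Inpatient
diagnoses weigh 2, outpatient 1 (configurable). Ties go to the subtype of
the last in-window diagnosis; a same-day tie goes to the later input row,
a documented convention since no intra-day ordering exists in day-granular
data. The outpatient-only gate (≥ 2 outpatient diagnoses when no inpatient
diagnosis is present) applies to the winning subtype's own outpatient
count, not the total.

Age is completed years (floor) at index; 12–17 gives the juvenile cohorts.

## Matching

Controls come from the pool of patients with no DM/PM diagnosis at any
time. Matching is 1:1 without replacement on birth year and sex; the
control inherits the case's exact index date (the simplest day convention
satisfying a same-month-and-year start) and must be database-active on it.
No minimum pre- or post-index activity is demanded of controls — activity
continuity is a case requirement, and demanding it of controls would
shrink the pool beyond what the design describes. Cases are processed in a
seeded random permutation and the control is drawn uniformly from the
remaining compatible candidates, so scarce controls are not awarded
systematically to early ids. Unmatched cases stay in cohort-level rate
analyses; only the matched-control comparison loses them.

## Follow-up and outcomes

Follow-up runs from index to the earliest of death, end of activity,
subtype switch, or study end; same-day ties resolve death >
end-of-activity > switch > study-end. For cases the switch trigger is one
inpatient or the second outpatient post-index diagnosis of the *other*
subtype (same-subtype diagnoses never censor). For controls a **single**
diagnosis of either subtype censors: the design language for controls is
unqualified ("any DM or PM diagnosis"), so the confirmation rule is not
applied to them. A control's follow-up is *not* truncated at its case's
censoring date — pair-symmetric truncation is nowhere implied, and person-
time is analysed per cohort, not per pair.

Each of the 13 outcomes is followed independently to its first occurrence
in the closed interval `[index, fu_end]`. An event inside the 12-month
pre-index washout `[index − 12 months, index)` removes the subject from
that outcome only. An event on the index date itself is incident at zero
days at risk (it is inside the post-index interval and outside the
half-open washout). All-cause death has no washout and is sourced from the
patient table's death date, not coded events. The two malignancy labels
are independent: a subject can be washout-ineligible for one and followed
for the other. Person-time is days / 365.25.

## Estimation

Crude rates are `ir_scale · k / T` (default per 100 person-years).
Intervals are exact Poisson (Garwood) bounds via chi-square quantiles —
the standard choice for rare outcomes, with a finite positive upper bound
at zero events; cells with zero eligible person-time are emitted flagged,
without rates. Progression summaries report the arithmetic mean years from
index to event among subjects with the event, plus crude cumulative
percentages of eligible subjects with an event by 6 months, 1 and 2 years:
subjects censored before a horizon remain in the denominator (no
survival adjustment — a deliberate, documented simplification; a
life-table estimator would shift the percentages upward under heavy early
censoring). Baseline tables flag diagnoses/procedures over
`[index − 12 months, index)` and medications over `[eaw_start, eaw_start +
7 months)` (the window plus the first post-index month), with sample
(n−1) standard deviations for continuous variables. Display rounding is
one decimal; machine outputs keep full precision.

## Calendar conventions

Dates are day-granular ISO-8601. `date + k months` clamps to the end of
the target month (Aug 31 + 6 months → Feb 28/29). All derived windows are
half-open `[start, end)` except where a contract states otherwise (the
study period and the event-observation interval are closed). Patient
activity is one continuous closed interval; multi-interval enrollment is
out of scope.

## The synthetic generator

`simulate_population` emulates the *statistical structure* the analysis
assumes, not real claims data:

- **Cases** draw a true subtype and a first-diagnosis date uniform over
  the feasible range (so window and activity margins are satisfiable by
  construction), then `n_eaw_dx` further in-window diagnoses, each
  inpatient with probability `inpatient_prob` and coded as the opposite
  subtype with probability `misclass_prob` (symmetric coding noise; the
  window-opening diagnosis is always true). Index ages are drawn inside
  the juvenile/adult bands with a margin so calendar completed-years never
  straddles a boundary. Outcome events are exponential first arrivals from
  index at the case rate; washout priors are injected with per-outcome
  probability; death and dropout compete as exponential clocks from index.
- **Background patients** are templated on cases (same birth year and sex,
  activity from before study start), which makes the matching pool ample
  by construction. Their outcome events are a full homogeneous Poisson
  process over the activity interval rather than a single first-arrival
  clock: a matched control's follow-up starts at its *case's* index date,
  and only a memoryless process guarantees the nominal control rate from
  an arbitrary anchor. Their washout priors arise from the same process.
- Explicit knobs (`prior_iim_prob`, `under_age_fraction`, `non_idn_prob`)
  generate patients that trip specific exclusion screens; all default to
  zero, so the base population is fully eligible and, at zero
  misclassification, recovered exactly.

The default scenario's hazards (0.005–0.103 events/PY, cases above
controls; e.g. GERD 0.103 vs 0.064) and washout-prior probabilities
(0.02–0.31) are magnitudes typical of extra-muscular manifestation rates
and baseline comorbidity prevalences in adult US dermatomyositis
populations; they anchor the simulation at a realistic operating point and
are not reproduction targets. Sex is 70% female (myositis is
female-predominant), the DM share of cases 0.48, the juvenile share 0.02,
dropout 0.15/PY and case/control death 0.022/0.008 per PY, giving mean
follow-up near 2 years over the 5.25-year study window.

Deliberately *not* emulated: ICD/NDC code vocabularies (events carry
category labels; code mapping is a separate, user-supplied step),
correlation between comorbidities, time-varying or covariate-dependent
hazards, contaminated control pools, multi-interval enrollment, and
seasonality. Passing tests therefore demonstrate correctness of the
*pipeline mechanics and estimators* under the stated assumptions, not
robustness to structure the generator does not contain.

## Validation design and problem sizes

- Window scoring is checked against an independently coded brute-force
  rule on all 2,340 diagnosis sequences of length ≤ 4 over subtype ×
  setting with every same-day tie configuration, and spot-checked
  end-to-end through the full cohort builder.
- Follow-up ends are checked against a literal day-by-day scan on 1,000
  randomized subjects covering deaths, dropout, both switch rules, and the
  control single-diagnosis rule.
- The Garwood bounds are checked against numeric inversion of the Poisson
  tail equations for 0–50 events (agreement ~1e−14 on the rate scale).
- Statistical recovery uses 200 replicates of 2,000 cases with a single
  constant-hazard outcome: observed case-rate bias is a fraction of a
  percent, 95% CI coverage sits at its nominal level, and the
  case-above-control ordering is recovered in every replicate. Replicate
  and population sizes were chosen to put Monte-Carlo error well below the
  effects being checked while keeping a full run in the minutes range on
  one CPU.

## Known limitations

- The tie convention for same-day "last diagnosis" and the
  single-diagnosis control censoring rule are documented choices on points
  the underlying design leaves open.
- Cumulative progression percentages ignore differential censoring.
- The generator's ample-by-construction pool means matching scarcity is
  exercised only in targeted unit tests, not at scale.
- No competing-risk handling: death censors non-fatal outcomes rather than
  being modelled jointly.
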