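"""Closed label sets used throughout the pipeline.

The two disease subtypes (dermatomyositis, polymyositis) define the
phenotyping problem; the 13 outcome labels are the extra-muscular
manifestations, malignancies, and all-cause death tracked during follow-up.
"""

SUBTYPES = ("DM", "PM")

#: adult cohort label -> juvenile cohort label (index age 12 to <18)
JUVENILE = {"DM": "JDM", "PM": "JPM"}

CASE_COHORTS = ("DM", "PM", "JDM", "JPM")

ALL_CAUSE_DEATH = "all_cause_death"

#: The closed set of outcomes followed post-index.
OUTCOMES = (
    "ILD",
    "ILD_requiring_oxygen",
    "heart_failure",
    "cardiomyopathy",
    "cardiac_dysrhythmia",
    "ischemic_heart_disease",
    "dysphagia",
    "esophageal_dysmotility",
    "GERD",
    "peptic_ulcer",
    "malignancy_excl_NMSC",
    "malignancy_main6",
    ALL_CAUSE_DEATH,
)


def other_subtype(subtype: str) -> str:
    if subtype == "DM":
        return "PM"
    if subtype == "PM":
        return "DM"
    raise ValueError(f"unknown subtype: {subtype!r}")


def control_group(cohort: str) -> str:
    """Group label for the matched controls of a case cohort."""
    if cohort not in CASE_COHORTS:
        raise ValueError(f"unknown cohort: {cohort!r}")
    return "MC_" + cohort
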