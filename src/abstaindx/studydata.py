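"""Published summary counts from the device's pivotal prospective
validation study (425 completers, 18-72 months, six US states).

Individual-level trial data are not public; the printed contingency
tables are, and every headline accuracy metric is an exact integer ratio
recomputable from them. The 3x3 confusion matrix ships as package data;
the stratified counts used for the published subgroup contrasts are the
constants below.
"""

from __future__ import annotations

from importlib import resources

from .stats import Confusion3x3

__all__ = [
    "study_confusion",
    "AGE_DETERMINATE",
    "AGE_SPECIFICITY",
    "SEX_SENSITIVITY",
    "PANEL_AGREEMENT",
]


def study_confusion() -> Confusion3x3:
    """The trial's device-output x reference-category count matrix
    (grand total 425; indeterminate row total 290)."""
    with resources.as_file(
            resources.files("abstaindx.data") / "study_confusion.csv") as p:
        return Confusion3x3.from_csv(p)


#: determinate outputs / subjects, by age group (under vs over 3 years)
AGE_DETERMINATE = {
    "18mo_3y": (72, 185),
    "3y_6y": (63, 240),
}

#: true negatives / reference-negative determinate subjects, by age group
AGE_SPECIFICITY = {
    "18mo_3y": (20, 30),
    "3y_6y": (36, 41),
}

#: determinate-subset sensitivity counts by sex
SEX_SENSITIVITY = {
    "female": (12, 13),
    "male": (51, 51),
}

#: consensus-panel agreement marginals: first reviewer agreed with the
#: diagnosing specialist 79% of the time; on disagreement the tie-breaker
#: sided with the diagnosing specialist 43% of the time; the diagnosing
#: specialist was somewhat-or-completely certain 95% of the time
PANEL_AGREEMENT = {
    "reviewer1_agreement": 0.79,
    "tiebreak_split": 0.43,
    "second_reviewer_rate": 0.21,
    "certainty_ge3_rate": 0.95,
}
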