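"""Consensus specialist reference-standard simulation.

The clinical reference standard in the study design this package models is
a DSM-5 diagnosis by a specialist, independently re-assessed by a blinded
reviewing specialist; on disagreement a second reviewer is consulted and
the majority of the (then three) binary ASD calls fixes the label. The
diagnosing specialist also reports a certainty Likert score (1 =
completely uncertain .. 4 = completely certain).

Two simulation modes are provided:

``agreement``
    Reviewer behavior is drawn directly from the published agreement
    marginals: the first reviewer agrees with the diagnosing specialist
    with probability ``reviewer1_agreement`` (default 0.79) and, on
    disagreement, the tie-breaking reviewer sides with the diagnosing
    specialist with probability ``tiebreak_split`` (default 0.43). This
    exactly reproduces printed agreement rates but is not generative with
    respect to truth.

``error_model``
    Each specialist independently errs against the subject's true class
    with a per-class probability; majority voting then reduces label
    noise (closed-form 3-voter majority error eps^2 * (3 - 2*eps) for
    symmetric independent errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CLASSES, ConfigError, Subject

__all__ = [
    "PanelParams",
    "RefDiagnosis",
    "adjudicate",
    "certainty_score",
    "adjudicate_cohort",
    "REF_LABELS",
]

REF_LABELS = (
    "ASD_positive",
    "ASD_negative_other_condition",
    "ASD_negative_neurotypical",
)

# Certainty defaults reproduce three published marginals simultaneously:
# "completely certain" 67% for ASD finals, 74% for other-condition finals,
# 95% for neurotypical finals, and "somewhat or completely certain"
# (level >= 3) 95% within every category, hence 95% overall.
DEFAULT_CERTAINTY = {
    "ASD_positive": (0.01, 0.04, 0.28, 0.67),
    "ASD_negative_other_condition": (0.01, 0.04, 0.21, 0.74),
    "ASD_negative_neurotypical": (0.01, 0.04, 0.00, 0.95),
}


@dataclass
class PanelParams:
    """Specialist-panel behavior parameters."""

    #: per-true-class probability an individual specialist call differs
    #: from truth. Default 0: in agreement mode all reference-label noise
    #: then derives from the published agreement marginals themselves
    #: (the final label flips the diagnosing call ~12% of the time);
    #: nonzero values are the sensitivity dial for error_model mode.
    specialist_error: dict = field(
        default_factory=lambda: {c: 0.0 for c in CLASSES})
    reviewer1_agreement: float = 0.79
    tiebreak_split: float = 0.43
    certainty_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CERTAINTY))
    mode: str = "agreement"  # or "error_model"

    def __post_init__(self) -> None:
        for c, e in self.specialist_error.items():
            if not 0.0 <= e <= 1.0:
                raise ConfigError(f"specialist_error[{c!r}] not in [0,1]")
        for p in (self.reviewer1_agreement, self.tiebreak_split):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("panel probabilities must be in [0,1]")
        for lab, dist in self.certainty_probs.items():
            d = np.asarray(dist, dtype=float)
            if d.shape != (4,) or np.any(d < 0) or abs(d.sum() - 1) > 1e-9:
                raise ConfigError(
                    f"certainty distribution for {lab!r} must be 4 "
                    "probabilities summing to 1")
        if self.mode not in ("agreement", "error_model"):
            raise ConfigError("mode must be 'agreement' or 'error_model'")


@dataclass(frozen=True)
class RefDiagnosis:
    """Adjudicated reference label with the panel trail."""

    final_label: str
    n_reviewers_used: int  # 1, or 2 when a tie-breaker was consulted
    diagnosing_call: bool  # individual binary ASD calls
    reviewer_calls: tuple[bool, ...]
    certainty: int  # Likert 1-4

    @property
    def is_asd(self) -> bool:
        return self.final_label == "ASD_positive"


def _negative_label(subject: Subject) -> str:
    # the panel is assumed to identify non-ASD conditions without error,
    # so the other-condition / neurotypical split follows the subject
    if subject.true_class == "comorbid_only" or subject.comorbidities:
        return "ASD_negative_other_condition"
    return "ASD_negative_neurotypical"


def certainty_score(final_label: str, panel: PanelParams,
                    rng: np.random.Generator) -> int:
    """Sample the diagnosing specialist's certainty Likert level (1-4)."""
    try:
        dist = panel.certainty_probs[final_label]
    except KeyError:
        raise ConfigError(
            f"no certainty distribution configured for {final_label!r}")
    return int(rng.choice(4, p=np.asarray(dist, dtype=float))) + 1


def adjudicate(subject: Subject, panel: PanelParams,
               rng: np.random.Generator) -> RefDiagnosis:
    """Run the consensus panel on one subject.

    The diagnosing specialist's binary ASD call errs against the true
    class with probability ``specialist_error[true_class]``. The first
    reviewer is then drawn per the panel mode; a tie-breaking reviewer is
    consulted exactly when the first two calls disagree, and the majority
    of the individual calls fixes the binary ASD status. Non-ASD finals
    are split into other-condition vs neurotypical by the subject.
    """
    truth = subject.true_class == "ASD"
    err_d = rng.random() < panel.specialist_error[subject.true_class]
    diagnosing = truth != err_d

    if panel.mode == "agreement":
        reviewer1 = (diagnosing if rng.random() < panel.reviewer1_agreement
                     else not diagnosing)
    else:
        err_r = rng.random() < panel.specialist_error[subject.true_class]
        reviewer1 = truth != err_r

    if reviewer1 == diagnosing:
        reviewers = (reviewer1,)
        final_asd = diagnosing
        n_rev = 1
    else:
        if panel.mode == "agreement":
            sides_with_diag = rng.random() < panel.tiebreak_split
            reviewer2 = diagnosing if sides_with_diag else reviewer1
        else:
            err_t = rng.random() < panel.specialist_error[subject.true_class]
            reviewer2 = truth != err_t
        reviewers = (reviewer1, reviewer2)
        votes = (diagnosing, reviewer1, reviewer2)
        final_asd = sum(votes) >= 2
        n_rev = 2

    final = "ASD_positive" if final_asd else _negative_label(subject)
    return RefDiagnosis(
        final_label=final,
        n_reviewers_used=n_rev,
        diagnosing_call=diagnosing,
        reviewer_calls=reviewers,
        certainty=certainty_score(final, panel, rng),
    )


def adjudicate_cohort(subjects: list[Subject], panel: PanelParams,
                      rng: np.random.Generator) -> list[RefDiagnosis]:
    """Adjudicate every subject, in cohort order, from one rng stream."""
    return [adjudicate(s, panel, rng) for s in subjects]
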