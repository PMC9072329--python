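"""Synthetic developmental-delay cohort generation.

Emulates the statistical structure of a primary-care cohort of
18--72-month-olds referred for developmental-delay concerns: three latent
clinical classes (ASD, non-ASD developmental/behavioral condition,
neurotypical) whose feature distributions overlap, age-banded 64-item
multimodal questionnaires generated from a graded (ordinal logistic)
item-response model, DSM-5 severity levels for ASD subjects, comorbidity
labels, and demographic covariates.

The comorbid (non-ASD condition) class sits *between* the neurotypical and
ASD classes on the latent severity trait; this overlap is what creates the
hard "indeterminate" zone that an abstaining classifier must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "Item",
    "ItemBank",
    "ClassLatent",
    "CohortConfig",
    "Subject",
    "assign_age_band",
    "graded_category_probs",
    "item_response",
    "generate_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "CLASSES",
    "CHANNELS",
]

CLASSES = ("ASD", "comorbid_only", "neurotypical")
CHANNELS = ("caregiver", "video_analyst", "hcp")

#: per-channel item counts for each age band; totals are 64 in both bands
BAND_COUNTS = {
    "A": (18, 33, 13),  # 18-47 months
    "B": (21, 28, 15),  # 48-72 months
}

AGE_MIN, AGE_MAX = 18, 72
BAND_SPLIT = 48  # first age (months) belonging to the older band

# condition labels and marginal frequencies among non-ASD developmental /
# behavioral diagnoses, mirroring the frequency ordering seen in referred
# primary-care samples (language disorders most common, psychiatric
# diagnoses rare at this age)
COMORBIDITY_PROBS = {
    "language_disorder": 0.574,
    "global_developmental_delay": 0.311,
    "adhd": 0.249,
    "phonological_disorder": 0.160,
    "anxiety_disorder": 0.082,
    "oppositional_defiant_disorder": 0.038,
    "stereotypic_movement_disorder": 0.031,
}

DEFAULT_COVARIATE_PROBS = {
    "sex": {"female": 0.362, "male": 0.638},
    # non-exclusive race/ethnicity: independent inclusion probabilities
    "race_ethnicity": {
        "white_non_hispanic": 0.539,
        "black": 0.145,
        "hispanic_or_latino": 0.130,
        "asian": 0.050,
        "hawaiian_or_pacific_islander": 0.004,
        "other": 0.015,
    },
    "income_band": {
        "lt_25k": 0.090,
        "25k_50k": 0.205,
        "50k_75k": 0.200,
        "75k_100k": 0.193,
        "100k_150k": 0.150,
        "ge_150k": 0.097,
        "unknown": 0.065,
    },
    "education_band": {
        "some_high_school": 0.031,
        "high_school": 0.105,
        "some_college": 0.228,
        "associate": 0.126,
        "bachelor": 0.323,
        "graduate": 0.187,
    },
}


class DomainError(ValueError):
    """Input outside the domain the device supports."""


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass(frozen=True)
class AgeBand:
    """Questionnaire version assigned by age."""

    band: str  # "A" (18-47 mo) or "B" (48-72 mo)
    channel_counts: tuple[int, int, int]  # (caregiver, video analyst, HCP)

    @property
    def total_items(self) -> int:
        return sum(self.channel_counts)


def assign_age_band(age_months: int) -> AgeBand:
    """Map an age in months to its questionnaire band and item counts.

    Ages 18-47 months receive band A (18 + 33 + 13 items); ages 48-72
    months receive band B (21 + 28 + 15 items). Both total 64 items.
    """
    if not AGE_MIN <= age_months <= AGE_MAX:
        raise DomainError(
            f"age {age_months} months outside supported range "
            f"[{AGE_MIN}, {AGE_MAX}]"
        )
    band = "A" if age_months < BAND_SPLIT else "B"
    return AgeBand(band, BAND_COUNTS[band])


@dataclass(frozen=True)
class Item:
    """One graded-response questionnaire item.

    ``discrimination`` is the slope a > 0; ``thresholds`` are the K-1
    strictly increasing category boundaries b_1 < ... < b_{K-1} on the
    latent-trait scale.
    """

    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.discrimination <= 0:
            raise ConfigError("item discrimination must be > 0")
        b = np.asarray(self.thresholds, dtype=float)
        if b.size < 1 or np.any(np.diff(b) <= 0):
            raise ConfigError("item thresholds must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ItemBank:
    """Item parameters per age band and input channel."""

    items: dict  # band -> {channel -> tuple[Item, ...]}

    def __post_init__(self) -> None:
        for band, counts in BAND_COUNTS.items():
            per_channel = self.items.get(band)
            if per_channel is None:
                raise ConfigError(f"item bank missing band {band!r}")
            got = tuple(len(per_channel[c]) for c in CHANNELS)
            if got != counts:
                raise ConfigError(
                    f"band {band!r} channel item counts {got} != required {counts}"
                )

    def band_items(self, band: str) -> tuple[Item, ...]:
        """All items of a band, concatenated in channel order."""
        return tuple(
            it for c in CHANNELS for it in self.items[band][c]
        )

    @classmethod
    def default(cls, n_levels: int = 5, seed: int = 7) -> "ItemBank":
        """A deterministic default bank: K-level items with moderate,
        varied discriminations (0.8-2.0) and item locations spread over
        the latent scale so no single item separates the classes."""
        rng = np.random.default_rng(seed)
        items: dict = {}
        for band, counts in BAND_COUNTS.items():
            items[band] = {}
            for channel, k in zip(CHANNELS, counts):
                built = []
                for _ in range(k):
                    a = float(rng.uniform(0.8, 2.0))
                    center = float(rng.normal(0.0, 0.9))
                    spread = float(rng.uniform(0.6, 1.1))
                    offsets = np.linspace(-(n_levels - 2) / 2,
                                          (n_levels - 2) / 2, n_levels - 1)
                    built.append(Item(a, tuple(center + spread * offsets)))
                items[band][channel] = tuple(built)
        return cls(items)


@dataclass(frozen=True)
class ClassLatent:
    """Class-conditional normal distribution of the latent trait z."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("latent sd must be >= 0")


DEFAULT_CLASS_LATENTS = {
    # comorbid-only sits between neurotypical and ASD, with extra spread
    # reflecting the heterogeneity of non-ASD developmental conditions
    "ASD": ClassLatent(1.8, 1.0),
    "comorbid_only": ClassLatent(0.0, 1.2),
    "neurotypical": ClassLatent(-2.0, 1.0),
}


@dataclass
class CohortConfig:
    """Everything needed to draw one reproducible synthetic cohort."""

    n_subjects: int = 425
    class_probs: tuple[float, float, float] = (0.287, 0.619, 0.094)
    age_range_months: tuple[int, int] = (AGE_MIN, AGE_MAX)
    class_latent_params: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_LATENTS))
    item_bank: ItemBank = field(default_factory=ItemBank.default)
    covariate_probs: dict = field(
        default_factory=lambda: DEFAULT_COVARIATE_PROBS)
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
            raise ConfigError("class_probs must be three probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError("class_probs must sum to 1 (tolerance 1e-12)")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        lo, hi = self.age_range_months
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ConfigError(
                f"age range must lie within [{AGE_MIN}, {AGE_MAX}]")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ConfigError("missing_prob must be in [0, 1]")
        for cls_name in CLASSES:
            if cls_name not in self.class_latent_params:
                raise ConfigError(f"missing latent params for {cls_name!r}")


@dataclass
class Subject:
    """One simulated child."""

    id: str
    age_months: int
    sex: str
    race_ethnicity: frozenset
    income_band: str
    education_band: str
    true_class: str
    z: float
    sc_severity: int | None  # social-communication DSM-5 level, ASD only
    rrb_severity: int | None  # restricted/repetitive behavior level
    comorbidities: frozenset
    responses: np.ndarray  # length-64 ordinal vector (band order)

    def __post_init__(self) -> None:
        band = assign_age_band(self.age_months)
        if len(self.responses) != band.total_items:
            raise ConfigError(
                f"subject {self.id}: {len(self.responses)} responses, "
                f"band requires {band.total_items}")
        is_asd = self.true_class == "ASD"
        if is_asd != (self.sc_severity is not None):
            raise ConfigError("severities present iff true_class is ASD")
        if is_asd != (self.rrb_severity is not None):
            raise ConfigError("severities present iff true_class is ASD")
        if self.true_class == "comorbid_only" and not self.comorbidities:
            raise ConfigError("comorbid_only subjects need >= 1 comorbidity")


def graded_category_probs(z, item: Item) -> np.ndarray:
    """Closed-form category probabilities of the graded response model.

    P(level >= k) = logistic(a * (z - b_k)) for k = 1..K-1; category
    probabilities are successive differences. Vectorized over z: returns
    shape (len(z), K) (or (K,) for scalar z).
    """
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    b = np.asarray(item.thresholds, dtype=float)
    # cumulative P(level >= k), with sentinels P(>=0)=1, P(>=K)=0
    cum = 1.0 / (1.0 + np.exp(-item.discrimination * (z_arr[:, None] - b[None, :])))
    cum = np.concatenate(
        [np.ones((len(z_arr), 1)), cum, np.zeros((len(z_arr), 1))], axis=1)
    probs = -np.diff(cum, axis=1)
    return probs[0] if np.isscalar(z) or np.ndim(z) == 0 else probs


def item_response(z, item: Item, rng: np.random.Generator):
    """Sample ordinal response level(s) in {0..K-1} from the graded model."""
    probs = np.atleast_2d(graded_category_probs(np.atleast_1d(z), item))
    u = rng.random(probs.shape[0])
    levels = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    return int(levels[0]) if np.ndim(z) == 0 else levels


def _draw_race_set(rng, probs: dict) -> frozenset:
    picked = frozenset(lab for lab, p in probs.items() if rng.random() < p)
    return picked if picked else frozenset({"unknown"})


def _severity_from_tertile(z_asd: np.ndarray, rng) -> np.ndarray:
    """DSM-5 support level 1-3 from within-class z tertiles, jittered."""
    if len(z_asd) == 0:
        return np.zeros(0, dtype=int)
    q1, q2 = np.quantile(z_asd, [1 / 3, 2 / 3])
    sev = 1 + (z_asd > q1).astype(int) + (z_asd > q2).astype(int)
    jitter = rng.random(len(sev)) < 0.2
    direction = rng.integers(0, 2, len(sev)) * 2 - 1
    sev = np.where(jitter, np.clip(sev + direction, 1, 3), sev)
    return sev.astype(int)


def generate_cohort(config: CohortConfig) -> list[Subject]:
    """Draw a fully reproducible synthetic cohort.

    Classes are multinomial with ``class_probs``; the latent trait z is
    class-conditionally normal; covariates are drawn independently of
    class; item responses follow the graded model per the subject's age
    band. Identical config (including seed) yields an identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return []

    classes = np.array(CLASSES)[rng.choice(3, size=n, p=config.class_probs)]
    z = np.array([
        rng.normal(config.class_latent_params[c].mean,
                   config.class_latent_params[c].sd)
        for c in classes
    ])
    lo, hi = config.age_range_months
    ages = rng.integers(lo, hi + 1, size=n)

    cp = config.covariate_probs
    sex_labels = list(cp["sex"])
    sexes = rng.choice(sex_labels, size=n, p=[cp["sex"][s] for s in sex_labels])
    inc_labels = list(cp["income_band"])
    incomes = rng.choice(inc_labels, size=n,
                         p=[cp["income_band"][s] for s in inc_labels])
    edu_labels = list(cp["education_band"])
    edus = rng.choice(edu_labels, size=n,
                      p=[cp["education_band"][s] for s in edu_labels])
    races = [_draw_race_set(rng, cp["race_ethnicity"]) for _ in range(n)]

    # severities for ASD subjects
    sc_sev = np.zeros(n, dtype=int)
    rrb_sev = np.zeros(n, dtype=int)
    asd_mask = classes == "ASD"
    sc_sev[asd_mask] = _severity_from_tertile(z[asd_mask], rng)
    rrb_sev[asd_mask] = _severity_from_tertile(z[asd_mask], rng)

    # comorbidities: guaranteed >= 1 for comorbid_only, optional for ASD
    labels = list(COMORBIDITY_PROBS)
    weights = np.array([COMORBIDITY_PROBS[lab] for lab in labels])
    comorbs: list[frozenset] = []
    for c in classes:
        if c == "comorbid_only":
            draw = rng.random(len(labels)) < weights
            if not draw.any():
                draw[rng.choice(len(labels), p=weights / weights.sum())] = True
            comorbs.append(frozenset(np.array(labels)[draw]))
        elif c == "ASD":
            draw = rng.random(len(labels)) < 0.4 * weights
            comorbs.append(frozenset(np.array(labels)[draw]))
        else:
            comorbs.append(frozenset())

    # item responses, vectorized per band and item
    responses = np.zeros((n, 64), dtype=float)
    for band in BAND_COUNTS:
        mask = np.array([assign_age_band(a).band == band for a in ages])
        if not mask.any():
            continue
        zb = z[mask]
        cols = np.zeros((mask.sum(), 64), dtype=float)
        for j, item in enumerate(config.item_bank.band_items(band)):
            cols[:, j] = item_response(zb, item, rng)
        responses[mask] = cols
    if config.missing_prob > 0:
        miss = rng.random(responses.shape) < config.missing_prob
        responses = np.where(miss, np.nan, responses)

    subjects = []
    for i in range(n):
        subjects.append(Subject(
            id=f"S{i:05d}",
            age_months=int(ages[i]),
            sex=str(sexes[i]),
            race_ethnicity=races[i],
            income_band=str(incomes[i]),
            education_band=str(edus[i]),
            true_class=str(classes[i]),
            z=float(z[i]),
            sc_severity=int(sc_sev[i]) if asd_mask[i] else None,
            rrb_severity=int(rrb_sev[i]) if asd_mask[i] else None,
            comorbidities=comorbs[i],
            responses=responses[i],
        ))
    return subjects


def cohort_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Tabular view: one row per subject, responses as columns q01..q64,
    set-valued fields serialized as semicolon-joined sorted labels."""
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "age_months": s.age_months,
            "sex": s.sex,
            "race_ethnicity": ";".join(sorted(s.race_ethnicity)),
            "income_band": s.income_band,
            "education_band": s.education_band,
            "true_class": s.true_class,
            "z": s.z,
            "sc_severity": s.sc_severity if s.sc_severity is not None else "",
            "rrb_severity": s.rrb_severity if s.rrb_severity is not None else "",
            "comorbidities": ";".join(sorted(s.comorbidities)),
        }
        for j in range(64):
            row[f"q{j + 1:02d}"] = s.responses[j]
        rows.append(row)
    cols = (["id", "age_months", "sex", "race_ethnicity", "income_band",
             "education_band", "true_class", "z", "sc_severity",
             "rrb_severity", "comorbidities"]
            + [f"q{j + 1:02d}" for j in range(64)])
    return pd.DataFrame(rows, columns=cols)


def write_cohort_csv(path, subjects: list[Subject]) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table (or any per-subject record CSV) back."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ConfigError("cohort CSV must have a header with an 'id' column")
    return df
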