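# Methods

This note documents the models, parameter choices, numerics and known
limitations of `abstaindx`. Nothing here states a number the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

Each simulated child has a true clinical class drawn from
(π_ASD, π_comorbid, π_NT) = (0.287, 0.619, 0.094) — the class mix of the
trial population the package models — and a one-dimensional latent
severity trait z that is class-conditionally normal:

| class            | mean | sd  |
|------------------|------|-----|
| neurotypical     | −2.0 | 1.0 |
| comorbid (non-ASD condition) | 0.0 | 1.2 |
| ASD              | +1.8 | 1.0 |

The comorbid class deliberately sits *between* neurotypical and ASD,
with extra spread reflecting the heterogeneity of non-ASD developmental
conditions. This single choice reproduces the central phenomenon of the
study design: children with non-ASD developmental/behavioral conditions
dominate the score region where an abstaining classifier cannot commit.
The means/sds are a design choice (nothing in the published material
constrains them); they were fixed once to give substantial but
incomplete overlap (ASD-vs-rest separation of roughly 1.2–1.7 latent
sd).

Questionnaire responses follow a graded (ordinal logistic) item-response
model with K = 5 levels: P(level ≥ k) = logistic(a·(z − b_k)) with
strictly increasing thresholds b. The default item bank is generated
deterministically (fixed internal seed): discriminations uniform in
0.8–2.0, item locations spread N(0, 0.9), threshold spacings 0.6–1.1 —
moderate, varied items so that no single item separates the classes.
Ages are uniform on 18–72 months; ages 18–47 receive the 64-item band
with channel counts (18, 33, 13) (caregiver / video analyst / clinician)
and ages 48–72 the band with (21, 28, 15). Covariates (sex,
non-exclusive race/ethnicity, parental income and education) are drawn
independently of class by default — the matching null for a study that
found no performance differences across these groups — with marginals
close to the published baseline table. ASD subjects receive DSM-5
support levels 1–3 for both the social-communication and
restricted/repetitive-behavior domains from within-class z tertiles with
20% jitter, linking severity monotonically to the latent trait.

What the generator does *not* emulate: real questionnaire wording or
content, video features, item-level dependence beyond the single latent
trait, class-dependent covariates, or enrollment/dropout dynamics.
Passing tests therefore show the machinery is correct under a
well-specified generative model, not that the device's real-world
operating characteristics are reproduced.

## Consensus reference standard

Two modes:

- **agreement** (default): the first reviewer agrees with the diagnosing
  specialist with probability 0.79; on disagreement a tie-breaker sides
  with the diagnosing specialist with probability 0.43, and the majority
  of the three binary calls fixes the label. This reproduces the
  published agreement marginals exactly — second-reviewer usage 21% and
  final-follows-diagnosing 0.79 + 0.21·0.43 = 0.8803 — but, because the
  disagreement events are independent of truth, it implies ≈12%
  truth-independent reference-label noise. That is an upper bound on
  the real panel's noise (real disagreements concentrate on genuinely
  ambiguous cases); it is the price of calibrating only to marginals.
  `specialist_error` defaults to 0 here so that all noise derives from
  the marginals rather than being double-counted.
- **error_model**: every specialist independently errs against the true
  class with a per-class probability; majority voting then reduces noise
  (closed-form 3-voter majority error ε²(3 − 2ε) for symmetric ε, which
  the tests verify by simulation). The per-class errors are a
  sensitivity dial, not estimates — individual-specialist accuracy
  against truth is unobservable in such trials.

Non-ASD finals split into "other condition" vs "neurotypical" by the
subject's own status (the panel is assumed to identify non-ASD
conditions without error). Certainty Likert scores (1–4) are sampled per
final category with defaults (level-4 mass 0.67 / 0.74 / 0.95 for ASD /
other-condition / neurotypical finals, each topped up to
P(level ≥ 3) = 0.95) chosen to satisfy all published certainty marginals
simultaneously; certainty is conditionally independent of the device
output given the final label, matching the study's null finding on that
comparison.

## Score model and abstention calibration

The score model is a gradient-boosted tree classifier (scikit-learn,
100 trees, depth 3, learning rate 0.1, fixed seed) behind a pluggable
interface; any `predict_proba` classifier substitutes (tests use
logistic regression where speed matters). One model is fit per age band;
out-of-fold scores from stratified K-fold (default 5) cross-validation
are pooled across bands for a single device-wide threshold pair.

Calibration maximizes the determinate rate subject to PPV ≥ 0.65 and
NPV ≥ 0.85 evaluated on the out-of-fold scores (pooled point estimates
by default; a per-fold mode requires every fold to satisfy the floors).
Numerical choices:

- **Candidate grid**: midpoints between consecutive sorted unique
  scores, plus {0, 1}. Metrics change only where a threshold crosses an
  observed score, so the grid is sufficient; the search over all
  O(m²) ordered pairs is vectorized with prefix sums.
- **Boundary convention**: negative iff s < t_neg, positive iff
  s ≥ t_pos; t_neg = t_pos collapses to an ordinary binary classifier.
- **Zero denominators**: a floor whose denominator is empty (no
  positives or no negatives) counts as *not* satisfied. This is the
  conservative reading; it prevents degenerate "bands" consisting of a
  single lucky subject from passing.
- **Tie-break**: among feasible coverage maximizers, the widest band,
  then the lowest t_neg — deterministic, and conservative in keeping
  with a design that minimizes false negatives.
- **Infeasibility** is a first-class return value
  (`CalibrationFailure`), not an exception: overlapping populations
  genuinely may admit no band meeting the floors. With labels
  independent of scores at prevalence 0.29 < the 0.65 PPV floor,
  feasibility depends only on the ordered label sequence (distribution-
  free in the score law); calibration then fails outright in ~73% of
  draws at n = 400 and returns negligible (< 5%) coverage in ~94%,
  with tiny lucky tails accounting for the remainder.

The objective (maximize coverage at the floors) is the standard
selective-classification choice; the real device's objective was not
disclosed and was likely more conservative, since a floor-tight band has
no margin against reference-standard noise (see the simulated-trial
example, where the observed NPV falls below the floor it satisfied on
clean training labels).

## Evaluation statistics

- 3×3 confusion matrix: device output (positive / indeterminate /
  negative) × reference category (ASD / other condition / neurotypical).
  TP = positive∧ASD; both non-ASD columns pool into the negative
  reference class (the arithmetic the published tables use).
- Determinate-subset metrics: PPV = TP/(TP+FP), NPV = TN/(TN+FN),
  Se = TP/(TP+FN), Sp = TN/(TN+FP) over determinate outputs only;
  determinate rate = determinate/total. No-abstention counterfactual:
  Se = TP/all reference-positives, Sp = TN/all reference-negatives —
  abstentions count as failures, as forced by the published
  denominators. Zero-denominator metrics carry an explicit undefined
  flag rather than propagating NaN.
- Clopper–Pearson intervals via beta quantiles
  (lo = B(α/2; x, n−x+1), hi = B(1−α/2; x+1, n−x)), exactly 0/1 at the
  boundaries; verified against independent bisection of the binomial
  tail conditions to 1e−6 for all n ≤ 25 and for conservative coverage
  by simulation.
- Boschloo's unconditional exact test: ordering statistic = Fisher exact
  p-value of matching sidedness (two-sided Fisher for the two-sided
  test, tie tolerance 1e−12 relative); p = sup over a nuisance grid of
  1000 equally spaced interior points with two local 10× refinement
  passes, bounding grid error well below reporting precision. Verified
  against full outcome-space enumeration with exact rational Fisher
  ordering for small tables, against the Fisher-dominance inequality,
  and against scipy's implementation (which orients samples as columns).
  The published subgroup p-values are reproduced under the two-sided
  convention (0.0060 and 0.0309); sidedness was not disclosed, so the
  one-sided values are available via `alternative=`.
- Stratified reports: one metrics report per stratum;
  race/ethnicity strata are non-exclusive (multi-category subjects count
  in every category they list); the comparability check is CI overlap,
  with no multiple-testing correction — a faithful-reproduction choice,
  not an endorsement.

## Pipeline

`simulate_full` emulates a prospective validation: the device (score
models + thresholds) is developed on a separate training cohort labeled
by true class — standing in for a developer's clinically confirmed
corpus — frozen, and applied to an independently generated trial cohort
whose labels come from the consensus panel. Problem sizes default to
1000 training subjects and 425 trial subjects. All randomness flows from
one seed through named substreams (training cohort, trial cohort, panel,
learner), runs are byte-identical under a fixed seed, and every run
directory logs the config hash, seed and calibration decisions.

## Known limitations

- The latent-trait model is unidimensional; real multimodal inputs
  (questionnaires plus video) have richer dependence, and the mapping of
  the 32 core behavioral constructs to the 64 items is not public, so
  items are exchangeable within channel.
- Agreement-mode reference noise is truth-independent by construction
  (see above); error-model mode exists precisely to explore
  truth-linked alternatives.
- The device analogue is not the proprietary device: no feature weights,
  no training corpus, no video pipeline. Quantities that depend only on
  the published counts are exact; everything generated is a structural
  emulation.
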