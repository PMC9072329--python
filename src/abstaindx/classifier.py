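"""Score model and dual-threshold abstention layer.

A probabilistic classifier (gradient-boosted trees by default, any
scikit-learn classifier with ``predict_proba`` substitutable) maps the
64-item feature vector to a score in [0, 1]; two thresholds
``t_neg <= t_pos`` partition the score axis into negative / indeterminate
/ positive. The thresholds are calibrated on *out-of-fold* cross-validated
scores to maximize the determinate rate (coverage) subject to PPV and NPV
floors — the selective-classification analogue of tuning an abstention
band against regulator-negotiated predictive-value minimums.

Boundary convention: negative iff score < t_neg; positive iff
score >= t_pos; indeterminate otherwise. With t_neg == t_pos the band is
empty and the classifier reduces to an ordinary binary one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScoreModel",
    "ThresholdPair",
    "FloorSpec",
    "OofScores",
    "CalibrationFailure",
    "fit_score_model",
    "cross_val_scores",
    "apply_thresholds",
    "classify",
    "calibrate_thresholds",
    "band_metrics",
    "default_learner",
]

DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
}


class FitError(ValueError):
    pass


def default_learner(hyperparams: dict | None = None, seed: int = 0):
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    return GradientBoostingClassifier(random_state=seed, **hp)


@dataclass
class ScoreModel:
    """A fitted predictor exposing score(X) -> [0,1], plus fit metadata."""

    estimator: object
    n_features: int
    hyperparams: dict
    seed: int
    band: str | None = None

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise FitError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} "
                f"columns, model was fit with {self.n_features}")
        return self.estimator.predict_proba(X)[:, 1]


def _validate_training(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise FitError("features must be a 2-D matrix (subjects x items)")
    if len(y) != X.shape[0]:
        raise FitError("feature/label length mismatch")
    if len(np.unique(y)) < 2:
        raise FitError("training set must contain both classes")
    return X, y


def fit_score_model(X, y, hyperparams: dict | None = None, seed: int = 0,
                    learner=None, band: str | None = None) -> ScoreModel:
    """Fit the score model (gradient-boosted trees unless ``learner`` is
    given). Deterministic for fixed data, hyperparameters and seed."""
    X, y = _validate_training(X, y)
    est = clone(learner) if learner is not None else default_learner(
        hyperparams, seed)
    if learner is not None and hasattr(est, "random_state"):
        est.set_params(random_state=seed)
    est.fit(X, y)
    return ScoreModel(est, X.shape[1], dict(hyperparams or DEFAULT_HYPERPARAMS),
                      seed, band)


@dataclass
class OofScores:
    """Out-of-fold cross-validated scores; the calibration input.

    ``out_of_fold`` is the provenance flag calibrate_thresholds checks:
    scores produced by any in-sample path must never be calibrated on.
    """

    scores: np.ndarray
    labels: np.ndarray
    fold_ids: np.ndarray
    out_of_fold: bool = True


def cross_val_scores(X, y, hyperparams: dict | None = None, seed: int = 0,
                     folds: int = 5, learner=None) -> OofScores:
    """Stratified K-fold out-of-fold scores for every subject."""
    X, y = _validate_training(X, y)
    if folds < 2:
        raise FitError("need >= 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1, dtype=int)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        model = fit_score_model(X[tr], y[tr], hyperparams, seed,
                                learner=learner)
        scores[te] = model.score(X[te])
        fold_ids[te] = k
    return OofScores(scores, y.copy(), fold_ids, out_of_fold=True)


@dataclass(frozen=True)
class ThresholdPair:
    """The abstention band: scores in [t_neg, t_pos) are indeterminate."""

    t_neg: float
    t_pos: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_neg <= self.t_pos <= 1.0:
            raise ValueError(
                f"need 0 <= t_neg <= t_pos <= 1, got ({self.t_neg}, {self.t_pos})")


@dataclass(frozen=True)
class FloorSpec:
    """PPV/NPV floors and how the cross-validated constraint is checked."""

    ppv_floor: float = 0.65
    npv_floor: float = 0.85
    cv_folds: int = 5
    constraint_mode: str = "pooled_oof"  # or "per_fold"

    def __post_init__(self) -> None:
        for f in (self.ppv_floor, self.npv_floor):
            if not 0.0 < f < 1.0:
                raise ValueError("floors must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.constraint_mode not in ("pooled_oof", "per_fold"):
            raise ValueError("constraint_mode must be pooled_oof or per_fold")


@dataclass(frozen=True)
class CalibrationFailure:
    """No threshold pair satisfies the floors — a first-class outcome for
    overlapping populations, not an error."""

    reason: str
    n_candidates: int


def apply_thresholds(score: float, thresholds: ThresholdPair) -> str:
    """Classify one score: negative / indeterminate / positive."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < thresholds.t_neg:
        return "negative"
    if score >= thresholds.t_pos:
        return "positive"
    return "indeterminate"


def classify(scores, thresholds: ThresholdPair) -> np.ndarray:
    """Vectorized apply_thresholds."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores outside [0, 1]")
    out = np.full(s.shape, "indeterminate", dtype=object)
    out[s < thresholds.t_neg] = "negative"
    out[s >= thresholds.t_pos] = "positive"
    return out


def band_metrics(scores, labels, thresholds: ThresholdPair) -> dict:
    """PPV, NPV and determinate rate of a threshold pair on scored data.
    Metrics with empty denominators are reported as nan."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s >= thresholds.t_pos
    neg = s < thresholds.t_neg
    tp, fp = int((pos & (y == 1)).sum()), int((pos & (y == 0)).sum())
    tn, fn = int((neg & (y == 0)).sum()), int((neg & (y == 1)).sum())
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return {
        "ppv": ppv, "npv": npv,
        "determinate_rate": (pos.sum() + neg.sum()) / len(s) if len(s) else
        float("nan"),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def _candidate_grid(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores, plus {0, 1}.

    Metrics only change where a threshold crosses an observed score, so
    this finite grid is sufficient."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def _pair_counts(scores, labels, cands):
    """For every candidate threshold c: counts of (FN, TN) below c and
    (TP, FP) at or above c, via prefix sums on the sorted scores."""
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    pos_prefix = np.concatenate([[0], np.cumsum(y_sorted)])
    n = len(scores)
    n_pos = int(pos_prefix[-1])
    idx = np.searchsorted(s_sorted, cands, side="left")
    below_pos = pos_prefix[idx]           # FN if c = t_neg
    below_neg = idx - below_pos           # TN if c = t_neg
    above_pos = n_pos - below_pos         # TP if c = t_pos
    above_neg = (n - idx) - above_pos     # FP if c = t_pos
    return idx, below_pos, below_neg, above_pos, above_neg, n


def _feasible_mask(scores, labels, cands, floors: FloorSpec):
    """Boolean (m, m) mask over (t_neg index, t_pos index) pairs meeting
    the floors, plus the determinate-rate matrix. A floor whose
    denominator is zero counts as NOT met (conservative)."""
    idx, fn, tn, tp, fp, n = _pair_counts(scores, labels, cands)
    m = len(cands)
    TP = tp[None, :].repeat(m, axis=0)
    FP = fp[None, :].repeat(m, axis=0)
    TN = tn[:, None].repeat(m, axis=1)
    FN = fn[:, None].repeat(m, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv_ok = (TP + FP > 0) & (TP / np.maximum(TP + FP, 1)
                                  >= floors.ppv_floor - 1e-12)
        npv_ok = (TN + FN > 0) & (TN / np.maximum(TN + FN, 1)
                                  >= floors.npv_floor - 1e-12)
    # determinate count = (# below t_neg) + (# at/above t_pos)
    det = idx[:, None] + (n - idx)[None, :]
    upper = cands[:, None] <= cands[None, :]  # enforce t_neg <= t_pos
    return ppv_ok & npv_ok & upper, det / n


def calibrate_thresholds(oof_scores, labels=None,
                         floors: FloorSpec = FloorSpec()):
    """Choose the abstention band maximizing determinate rate under the
    PPV/NPV floors, searched over the sufficient candidate grid.

    Accepts an :class:`OofScores` (preferred — carries the out-of-fold
    provenance flag) or raw ``(scores, labels)`` arrays. Returns a
    :class:`ThresholdPair`, or a :class:`CalibrationFailure` when no pair
    is feasible. Ties on determinate rate break toward the widest band
    (most conservative), then the lowest t_neg.
    """
    if isinstance(oof_scores, OofScores):
        if not oof_scores.out_of_fold:
            raise ValueError(
                "calibration requires out-of-fold scores; in-fold scores "
                "were passed (out_of_fold flag is False)")
        scores = np.asarray(oof_scores.scores, dtype=float)
        y = np.asarray(oof_scores.labels).astype(int)
        fold_ids = oof_scores.fold_ids
    else:
        if labels is None:
            raise ValueError("labels required when passing raw scores")
        scores = np.asarray(oof_scores, dtype=float)
        y = np.asarray(labels).astype(int)
        fold_ids = None
    if len(scores) == 0:
        raise ValueError("empty calibration input")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores outside [0, 1]")

    cands = _candidate_grid(scores)
    feasible, det_rate = _feasible_mask(scores, y, cands, floors)

    if floors.constraint_mode == "per_fold":
        if fold_ids is None:
            raise ValueError("per_fold constraint mode requires OofScores "
                             "with fold assignments")
        for k in np.unique(fold_ids):
            sel = fold_ids == k
            f_k, _ = _feasible_mask(scores[sel], y[sel], cands, floors)
            feasible &= f_k

    if not feasible.any():
        return CalibrationFailure(
            reason="no threshold pair meets the PPV/NPV floors on the "
                   "out-of-fold scores",
            n_candidates=len(cands))

    rate = np.where(feasible, det_rate, -1.0)
    best = rate.max()
    ii, jj = np.nonzero(rate >= best - 1e-15)
    width = cands[jj] - cands[ii]
    order = np.lexsort((cands[ii], -width))  # widest band, then lowest t_neg
    i, j = ii[order[0]], jj[order[0]]
    return ThresholdPair(float(cands[i]), float(cands[j]))
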