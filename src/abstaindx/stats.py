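"""Exact-statistics evaluation of a three-output diagnostic device.

Everything here operates on the 3x3 contingency table of device output
(positive / indeterminate / negative) against the adjudicated reference
category (ASD positive / ASD negative with another condition / ASD
negative and neurotypical), or on per-subject record tables.

Definitions
-----------
PPV, NPV, sensitivity and specificity are computed on the *determinate*
subset (abstentions excluded); TP = positive & ASD, and both non-ASD
reference columns pool into the "negative" reference class. The
no-abstention counterfactual instead counts every abstention as a failure
for its reference class, i.e. sensitivity = TP / all reference-positive
subjects and specificity = TN / all reference-negative subjects.

Interval estimates are exact Clopper-Pearson (central binomial
tail-inversion) intervals; subgroup contrasts use Boschloo's unconditional
exact test with the Fisher exact p-value as ordering statistic and a
supremum over a nuisance-probability grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, binom, hypergeom

__all__ = [
    "DEVICE_OUTPUTS",
    "REF_CATEGORIES",
    "Confusion3x3",
    "Proportion",
    "MetricsReport",
    "build_confusion",
    "determinate_metrics",
    "no_abstention_metrics",
    "metrics_report",
    "clopper_pearson",
    "boschloo_test",
    "BoschlooResult",
    "fisher_pvalue_grid",
    "stratified_metrics",
    "cis_overlap",
    "indeterminate_composition",
    "IndeterminateComposition",
    "pct1",
    "pct0",
    "table3_markdown",
    "table4_frame",
]

DEVICE_OUTPUTS = ("positive", "indeterminate", "negative")
REF_CATEGORIES = (
    "ASD_positive",
    "ASD_negative_other_condition",
    "ASD_negative_neurotypical",
)


# --------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Confusion3x3:
    """Device output (rows) x reference category (columns) count matrix."""

    counts: np.ndarray  # shape (3, 3), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            bad = np.argwhere(np.asarray(c) < 0)
            if bad.size:
                r, col = bad[0]
                raise ValueError(
                    f"negative count at device output {DEVICE_OUTPUTS[r]!r}, "
                    f"reference {REF_CATEGORIES[col]!r}")
            raise ValueError("confusion counts must be integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    def __getitem__(self, key):
        out, ref = key
        return int(self.counts[DEVICE_OUTPUTS.index(out),
                               REF_CATEGORIES.index(ref)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> dict:
        return {o: int(t) for o, t in zip(DEVICE_OUTPUTS,
                                          self.counts.sum(axis=1))}

    def col_totals(self) -> dict:
        return {r: int(t) for r, t in zip(REF_CATEGORIES,
                                          self.counts.sum(axis=0))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(DEVICE_OUTPUTS),
                            columns=list(REF_CATEGORIES))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("device_output").to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Confusion3x3":
        if list(df.index) != list(DEVICE_OUTPUTS):
            raise ValueError(
                f"row labels must be {list(DEVICE_OUTPUTS)}, got "
                f"{list(df.index)}")
        if list(df.columns) != list(REF_CATEGORIES):
            raise ValueError(
                f"column labels must be {list(REF_CATEGORIES)}, got "
                f"{list(df.columns)}")
        vals = df.to_numpy()
        neg = np.argwhere(vals < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(
                f"negative count at row {DEVICE_OUTPUTS[r]!r}, column "
                f"{REF_CATEGORIES[c]!r}")
        return cls(vals.astype(np.int64))

    @classmethod
    def from_csv(cls, path) -> "Confusion3x3":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df)

    def to_records(self) -> list[tuple[str, str]]:
        """Expand the matrix back into one (output, category) pair per
        subject, in row-major cell order."""
        recs = []
        for i, out in enumerate(DEVICE_OUTPUTS):
            for j, ref in enumerate(REF_CATEGORIES):
                recs.extend([(out, ref)] * int(self.counts[i, j]))
        return recs


def build_confusion(records) -> Confusion3x3:
    """Tally (device_output, ref_category) pairs into a Confusion3x3."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for out, ref in records:
        try:
            i = DEVICE_OUTPUTS.index(out)
        except ValueError:
            raise ValueError(f"unknown device output label {out!r}")
        try:
            j = REF_CATEGORIES.index(ref)
        except ValueError:
            raise ValueError(f"unknown reference category label {ref!r}")
        counts[i, j] += 1
    return Confusion3x3(counts)


@dataclass(frozen=True)
class Proportion:
    """A count ratio with its exact two-sided confidence interval."""

    numerator: int
    denominator: int
    point: float
    ci_lo: float
    ci_hi: float
    undefined: bool = False

    @classmethod
    def from_counts(cls, x: int, n: int, alpha: float = 0.05) -> "Proportion":
        if n == 0:
            return cls(0, 0, float("nan"), float("nan"), float("nan"),
                       undefined=True)
        lo, hi = clopper_pearson(x, n, alpha)
        return cls(int(x), int(n), x / n, lo, hi)

    def to_dict(self) -> dict:
        return {
            "num": self.numerator, "den": self.denominator,
            "point": self.point, "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            "undefined_flag": self.undefined,
        }


@dataclass
class MetricsReport:
    """Point estimates with exact CIs for the abstention-aware endpoints."""

    ppv: Proportion
    npv: Proportion
    sensitivity: Proportion
    specificity: Proportion
    determinate_rate: Proportion
    no_abstention_sensitivity: Proportion | None = None
    no_abstention_specificity: Proportion | None = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        out = {}
        for name in ("ppv", "npv", "sensitivity", "specificity",
                     "determinate_rate", "no_abstention_sensitivity",
                     "no_abstention_specificity"):
            p = getattr(self, name)
            if p is not None:
                out[name] = p.to_dict()
        out["alpha"] = self.alpha
        return out


# --------------------------------------------------------------------------
# Clopper-Pearson

def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact central two-sided binomial confidence interval.

    Beta-quantile form of inverting the binomial tails; the lower bound is
    exactly 0 when x = 0 and the upper bound exactly 1 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


# --------------------------------------------------------------------------
# confusion-matrix metrics

def _determinate_cells(C: Confusion3x3) -> tuple[int, int, int, int]:
    tp = C["positive", "ASD_positive"]
    fp = (C["positive", "ASD_negative_other_condition"]
          + C["positive", "ASD_negative_neurotypical"])
    fn = C["negative", "ASD_positive"]
    tn = (C["negative", "ASD_negative_other_condition"]
          + C["negative", "ASD_negative_neurotypical"])
    return tp, fp, tn, fn


def determinate_metrics(C: Confusion3x3, alpha: float = 0.05) -> MetricsReport:
    """PPV/NPV/Se/Sp on the determinate subset plus the determinate rate.

    Zero-denominator metrics come back flagged ``undefined`` rather than
    silently dropped.
    """
    if C.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = _determinate_cells(C)
    return MetricsReport(
        ppv=Proportion.from_counts(tp, tp + fp, alpha),
        npv=Proportion.from_counts(tn, tn + fn, alpha),
        sensitivity=Proportion.from_counts(tp, tp + fn, alpha),
        specificity=Proportion.from_counts(tn, tn + fp, alpha),
        determinate_rate=Proportion.from_counts(
            tp + fp + tn + fn, C.total, alpha),
        alpha=alpha,
    )


def no_abstention_metrics(C: Confusion3x3,
                          alpha: float = 0.05) -> tuple[Proportion, Proportion]:
    """Counterfactual sensitivity/specificity with the indeterminate
    output removed: abstentions count as failures for both classes, so
    the denominators are all reference-positive and all reference-negative
    subjects."""
    if C.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = _determinate_cells(C)
    col = C.col_totals()
    n_pos = col["ASD_positive"]
    n_neg = (col["ASD_negative_other_condition"]
             + col["ASD_negative_neurotypical"])
    return (Proportion.from_counts(tp, n_pos, alpha),
            Proportion.from_counts(tn, n_neg, alpha))


def metrics_report(C: Confusion3x3, alpha: float = 0.05) -> MetricsReport:
    """Full report: determinate metrics plus the no-abstention
    counterfactual."""
    rep = determinate_metrics(C, alpha)
    se_all, sp_all = no_abstention_metrics(C, alpha)
    rep.no_abstention_sensitivity = se_all
    rep.no_abstention_specificity = sp_all
    return rep


@dataclass(frozen=True)
class IndeterminateComposition:
    """What the device abstained on, by reference category."""

    fraction_neurodevelopmental: float  # >= 1 neurodev/behavioral diagnosis
    breakdown: tuple[float, float, float]  # per REF_CATEGORIES order
    row_total: int
    undefined: bool = False


def indeterminate_composition(C: Confusion3x3) -> IndeterminateComposition:
    """Fraction of abstained subjects holding at least one
    neurodevelopmental or behavioral diagnosis (ASD or otherwise)."""
    row = C.counts[DEVICE_OUTPUTS.index("indeterminate")]
    total = int(row.sum())
    if total == 0:
        return IndeterminateComposition(float("nan"), (float("nan"),) * 3, 0,
                                        undefined=True)
    frac = (row[0] + row[1]) / total
    return IndeterminateComposition(
        float(frac), tuple(float(c) / total for c in row), total)


# --------------------------------------------------------------------------
# Boschloo's unconditional exact test

def fisher_pvalue_grid(n1: int, n2: int, alternative: str) -> np.ndarray:
    """Fisher exact p-values for every outcome of two independent
    binomials: entry [x1, x2] is the p-value of the table with x1 of n1
    successes in group 1 and x2 of n2 in group 2.

    Conditional on the success total s = x1 + x2, x1 is hypergeometric;
    'less'/'greater' are tail sums over x1 and 'two-sided' sums all
    outcomes in the conditional distribution whose probability does not
    exceed that of the observed one (with a 1e-12 relative tie tolerance).
    """
    P = np.ones((n1 + 1, n2 + 1))
    for s in range(n1 + n2 + 1):
        amin, amax = max(0, s - n2), min(n1, s)
        avals = np.arange(amin, amax + 1)
        pmf = hypergeom.pmf(avals, n1 + n2, s, n1)
        if alternative == "less":
            pv = np.cumsum(pmf)
        elif alternative == "greater":
            pv = np.cumsum(pmf[::-1])[::-1]
        elif alternative == "two-sided":
            pv = np.array([pmf[pmf <= p * (1 + 1e-12)].sum() for p in pmf])
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        P[avals, s - avals] = np.minimum(pv, 1.0)
    return P


@dataclass(frozen=True)
class BoschlooResult:
    pvalue: float
    fisher_pvalue: float
    nuisance_at_sup: float
    degenerate: bool = False


def boschloo_test(table, alternative: str = "two-sided",
                  grid_size: int = 1000, refinements: int = 2) -> BoschlooResult:
    """Boschloo's unconditional exact test for a 2x2 table.

    ``table`` is [[x1, n1 - x1], [x2, n2 - x2]]: rows are the two groups,
    columns successes/failures. The ordering statistic is the Fisher
    exact p-value of the matching sidedness ('less' tests p1 < p2); the
    p-value is the supremum over the common nuisance success probability
    of the chance of an outcome at least as extreme:

        p = sup_pi P_pi( fisher_p(X1, X2) <= fisher_p(x1, x2) )

    evaluated on ``grid_size`` equally spaced interior points with
    ``refinements`` local 10x refinement passes around the supremum.
    Degenerate margins (an empty group, or all successes / all failures)
    return p = 1 with the ``degenerate`` flag set.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2")
    x1, f1 = int(t[0, 0]), int(t[0, 1])
    x2, f2 = int(t[1, 0]), int(t[1, 1])
    n1, n2 = x1 + f1, x2 + f2
    if n1 == 0 or n2 == 0 or x1 + x2 == 0 or f1 + f2 == 0:
        return BoschlooResult(1.0, 1.0, float("nan"), degenerate=True)

    F = fisher_pvalue_grid(n1, n2, alternative)
    obs = float(F[x1, x2])
    mask = F <= obs * (1 + 1e-12)
    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)

    def rejection_prob(pis: np.ndarray) -> np.ndarray:
        out = np.empty(len(pis))
        for i, pi in enumerate(pis):
            p1 = binom.pmf(k1, n1, pi)
            p2 = binom.pmf(k2, n2, pi)
            out[i] = float(p1 @ mask @ p2)
        return out

    pis = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    vals = rejection_prob(pis)
    best_pi = float(pis[np.argmax(vals)])
    best = float(vals.max())
    step = 1.0 / (grid_size + 1)
    for _ in range(refinements):
        lo = max(best_pi - step, 1e-12)
        hi = min(best_pi + step, 1 - 1e-12)
        pis = np.linspace(lo, hi, 201)
        vals = rejection_prob(pis)
        if vals.max() > best:
            best = float(vals.max())
            best_pi = float(pis[np.argmax(vals)])
        step /= 10.0
    return BoschlooResult(min(best, 1.0), obs, best_pi)


# --------------------------------------------------------------------------
# stratified reports

def _records_to_confusion(df: pd.DataFrame) -> Confusion3x3:
    return build_confusion(
        zip(df["device_output"].tolist(), df["ref_category"].tolist()))


def stratified_metrics(records: pd.DataFrame, covariate: str,
                       alpha: float = 0.05,
                       non_exclusive: bool | None = None) -> dict:
    """Per-stratum metrics reports for one covariate.

    ``records`` needs columns device_output, ref_category and the
    covariate. Semicolon-joined covariate values are treated as
    non-exclusive set membership (the race/ethnicity convention): a
    multi-category subject contributes to every category it lists.
    Empty strata yield reports whose metrics are all flagged undefined.
    """
    if covariate not in records.columns:
        raise ValueError(f"covariate {covariate!r} missing from records")
    vals = records[covariate].astype(str)
    if non_exclusive is None:
        non_exclusive = vals.str.contains(";").any()
    out: dict = {}
    if non_exclusive:
        strata = sorted({lab for v in vals for lab in v.split(";") if lab})
        for lab in strata:
            sel = vals.str.split(";").apply(lambda s: lab in s)
            out[lab] = metrics_report(_records_to_confusion(records[sel]),
                                      alpha)
    else:
        for lab in sorted(vals.unique()):
            out[lab] = metrics_report(_records_to_confusion(
                records[vals == lab]), alpha)
    return out


def cis_overlap(reports: dict, metric: str) -> bool:
    """The comparability check used for covariate analyses: do the 95%
    CIs of one metric overlap across every pair of (defined) strata?"""
    intervals = []
    for rep in reports.values():
        p: Proportion = getattr(rep, metric)
        if p is not None and not p.undefined:
            intervals.append((p.ci_lo, p.ci_hi))
    return all(a_lo <= b_hi and b_lo <= a_hi
               for i, (a_lo, a_hi) in enumerate(intervals)
               for (b_lo, b_hi) in intervals[i + 1:])


# --------------------------------------------------------------------------
# report formatting

def pct1(x: float) -> str:
    """One-decimal percent (overall-table style)."""
    return "" if math.isnan(x) else f"{x * 100:.1f}%"


def pct0(x: float) -> str:
    """Whole-number percent (stratified-table style)."""
    return "" if math.isnan(x) else f"{x * 100:.0f}%"


def table3_markdown(C: Confusion3x3) -> str:
    """Confusion matrix with cell percentages of the grand total, in the
    overall-results table style (counts with one-decimal percents)."""
    total = C.total
    lines = ["| Device output | " + " | ".join(REF_CATEGORIES) + " | Total |",
             "|" + "---|" * 5]
    for i, out in enumerate(DEVICE_OUTPUTS):
        cells = [f"{c} ({pct1(c / total)})" for c in C.counts[i]]
        row_tot = int(C.counts[i].sum())
        lines.append(f"| {out} | " + " | ".join(cells)
                     + f" | {row_tot} ({pct1(row_tot / total)}) |")
    col = C.counts.sum(axis=0)
    lines.append("| Total | "
                 + " | ".join(f"{c} ({pct1(c / total)})" for c in col)
                 + f" | {total} (100.0%) |")
    return "\n".join(lines)


def table4_frame(reports: dict) -> pd.DataFrame:
    """Stratified performance table (whole-percent style with counts and
    CIs), one row per stratum."""
    rows = []
    for stratum, rep in reports.items():
        row = {"stratum": stratum}
        for name in ("ppv", "npv", "determinate_rate", "sensitivity",
                     "specificity"):
            p: Proportion = getattr(rep, name)
            if p.undefined:
                row[name] = "-"
                row[f"{name}_ci"] = "-"
            else:
                row[name] = f"{pct0(p.point)} ({p.numerator}/{p.denominator})"
                row[f"{name}_ci"] = f"({pct0(p.ci_lo)}, {pct0(p.ci_hi)})"
        rows.append(row)
    return pd.DataFrame(rows)
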