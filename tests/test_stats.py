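"""Exact-statistics engine: confusion tallies, determinate and
no-abstention metrics, Clopper-Pearson intervals against a tail-inversion
oracle, Boschloo's test against full-enumeration and scipy cross-checks,
and stratified reports."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist
from scipy.stats import binom, boschloo_exact

from abstaindx import (Confusion3x3, build_confusion, boschloo_test,
                       clopper_pearson, determinate_metrics,
                       indeterminate_composition, metrics_report,
                       no_abstention_metrics, stratified_metrics)
from abstaindx.stats import (DEVICE_OUTPUTS, REF_CATEGORIES, cis_overlap,
                             pct0, pct1, table3_markdown, table4_frame)


# --------------------------------------------------------------------------
# confusion construction

def test_trial_records_rebuild_published_matrix(table3):
    C = build_confusion(table3.to_records())
    assert np.array_equal(C.counts, table3.counts)
    assert C.total == 425
    assert C.row_totals()["indeterminate"] == 290
    assert C.col_totals() == {"ASD_positive": 122,
                              "ASD_negative_other_condition": 263,
                              "ASD_negative_neurotypical": 40}


def test_empty_and_conservation(rng):
    assert build_confusion([]).total == 0
    recs = [(DEVICE_OUTPUTS[i], REF_CATEGORIES[j])
            for i, j in zip(rng.integers(0, 3, 50), rng.integers(0, 3, 50))]
    assert build_confusion(recs).total == len(recs)


def test_unknown_labels_named_in_error():
    with pytest.raises(ValueError, match="'maybe'"):
        build_confusion([("maybe", "ASD_positive")])
    with pytest.raises(ValueError, match="'ASD'"):
        build_confusion([("positive", "ASD")])


# --------------------------------------------------------------------------
# metrics

def test_published_counts_give_exact_ratios(table3):
    rep = determinate_metrics(table3)
    assert (rep.ppv.numerator, rep.ppv.denominator) == (63, 78)
    assert (rep.npv.numerator, rep.npv.denominator) == (56, 57)
    assert (rep.sensitivity.numerator, rep.sensitivity.denominator) == (63, 64)
    assert (rep.specificity.numerator, rep.specificity.denominator) == (56, 71)
    assert (rep.determinate_rate.numerator,
            rep.determinate_rate.denominator) == (135, 425)
    se_all, sp_all = no_abstention_metrics(table3)
    assert (se_all.numerator, se_all.denominator) == (63, 122)
    assert (sp_all.numerator, sp_all.denominator) == (56, 303)


def test_diagonal_matrix_is_perfect():
    C = Confusion3x3(np.diag([10, 0, 20]))
    rep = determinate_metrics(C)
    for name in ("ppv", "npv", "sensitivity", "specificity",
                 "determinate_rate"):
        assert getattr(rep, name).point == 1.0


def test_metrics_match_expansion_oracle(rng):
    """Random matrices: every metric equals a naive per-record recount."""
    for _ in range(20):
        C = Confusion3x3(rng.integers(0, 30, (3, 3)))
        if C.total == 0:
            continue
        recs = C.to_records()
        tp = sum(1 for o, r in recs if o == "positive" and r == "ASD_positive")
        fp = sum(1 for o, r in recs if o == "positive" and r != "ASD_positive")
        tn = sum(1 for o, r in recs if o == "negative" and r != "ASD_positive")
        fn = sum(1 for o, r in recs if o == "negative" and r == "ASD_positive")
        rep = determinate_metrics(C)
        if tp + fp:
            assert rep.ppv.point == tp / (tp + fp)
        else:
            assert rep.ppv.undefined
        if tn + fn:
            assert rep.npv.point == tn / (tn + fn)
        if tp + fn:
            assert rep.sensitivity.point == tp / (tp + fn)
        assert rep.determinate_rate.point == (tp + fp + tn + fn) / len(recs)
        se_all, sp_all = no_abstention_metrics(C)
        n_pos = sum(1 for _, r in recs if r == "ASD_positive")
        if n_pos:
            assert se_all.point == tp / n_pos
            if tp + fn:
                assert se_all.point <= rep.sensitivity.point + 1e-12


def test_no_abstention_equals_determinate_without_abstention():
    counts = np.array([[30, 5, 1], [0, 0, 0], [2, 40, 10]])
    C = Confusion3x3(counts)
    rep = determinate_metrics(C)
    se_all, sp_all = no_abstention_metrics(C)
    assert se_all.point == rep.sensitivity.point
    assert sp_all.point == rep.specificity.point


def test_zero_denominator_flagged_not_dropped():
    C = Confusion3x3(np.array([[0, 0, 0], [5, 5, 5], [1, 2, 3]]))
    rep = determinate_metrics(C)
    assert rep.ppv.undefined
    assert not rep.npv.undefined
    d = rep.to_dict()
    assert d["ppv"]["undefined_flag"] is True


# --------------------------------------------------------------------------
# Clopper-Pearson

def test_printed_interval_examples():
    lo, hi = clopper_pearson(63, 78)
    assert (round(lo, 3), round(hi, 3)) == (0.703, 0.888)
    assert clopper_pearson(0, 57)[0] == 0.0
    assert clopper_pearson(57, 57)[1] == 1.0
    with pytest.raises(ValueError):
        clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson(-1, 4)


def cp_bisection_oracle(x, n, alpha=0.05):
    """Independent tail-inversion: lo solves P(X >= x | p) = alpha/2,
    hi solves P(X <= x | p) = alpha/2."""
    lo = 0.0 if x == 0 else brentq(
        lambda p: binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-12)
    hi = 1.0 if x == n else brentq(
        lambda p: binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-12)
    return lo, hi


def test_clopper_pearson_matches_tail_inversion_all_small_n():
    for n in range(1, 26):
        for x in range(n + 1):
            got = clopper_pearson(x, n)
            want = cp_bisection_oracle(x, n)
            assert got == pytest.approx(want, abs=1e-6)


def test_clopper_pearson_coverage_is_conservative(rng):
    """Empirical coverage >= nominal 95% at each (n, p) combination,
    2000 simulated binomials each."""
    reps = 2000
    for n in (10, 50, 200):
        for p in (0.1, 0.5, 0.9):
            x = rng.binomial(n, p, size=reps)
            lo = np.where(x == 0, 0.0, beta_dist.ppf(0.025, x, n - x + 1))
            hi = np.where(x == n, 1.0, beta_dist.ppf(0.975, x + 1, n - x))
            coverage = np.mean((lo <= p) & (p <= hi))
            # allow 3 MC SEs below the exact coverage floor
            assert coverage >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / reps)


# --------------------------------------------------------------------------
# Boschloo

def exact_fisher_pvals(n1, n2, alternative):
    """Oracle Fisher p-values in exact rational arithmetic."""
    P = {}
    for s in range(n1 + n2 + 1):
        support = range(max(0, s - n2), min(n1, s) + 1)
        w = {a: Fraction(comb(n1, a) * comb(n2, s - a)) for a in support}
        tot = sum(w.values())
        for a in support:
            if alternative == "less":
                num = sum(w[b] for b in support if b <= a)
            elif alternative == "greater":
                num = sum(w[b] for b in support if b >= a)
            else:
                num = sum(w[b] for b in support if w[b] <= w[a])
            P[(a, s - a)] = num / tot
    return P


def oracle_boschloo(x1, n1, x2, n2, alternative, pis):
    """Full outcome-space enumeration at each nuisance grid point, with
    exact-rational Fisher ordering."""
    F = exact_fisher_pvals(n1, n2, alternative)
    obs = F[(x1, x2)]
    extreme = [(a, b) for (a, b) in F if F[(a, b)] <= obs]
    best = 0.0
    for pi in pis:
        tot = sum(binom.pmf(a, n1, pi) * binom.pmf(b, n2, pi)
                  for a, b in extreme)
        best = max(best, tot)
    return best


@pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
def test_boschloo_matches_full_enumeration(alternative, rng):
    """Small-table agreement with the exact-enumeration oracle on the
    same nuisance grid, tolerance 1e-9 (no refinement passes so the
    grids coincide)."""
    grid = np.linspace(0, 1, 52)[1:-1]
    for n1, n2 in [(3, 4), (5, 5), (8, 6), (2, 8), (7, 7)]:
        for _ in range(4):
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            if x1 + x2 == 0 or (n1 - x1) + (n2 - x2) == 0:
                continue
            got = boschloo_test([[x1, n1 - x1], [x2, n2 - x2]], alternative,
                                grid_size=50, refinements=0)
            want = oracle_boschloo(x1, n1, x2, n2, alternative, grid)
            assert got.pvalue == pytest.approx(want, abs=1e-9)


def test_boschloo_never_exceeds_fisher_one_sided(rng):
    """Uniform improvement over Fisher: boschloo_p <= fisher_p for every
    one-sided alternative (Fisher p is itself a valid p-value, so the
    supremum of the rejection probability cannot exceed it)."""
    for _ in range(60):
        n1 = int(rng.integers(1, 9))
        n2 = int(rng.integers(1, 9))
        x1 = int(rng.integers(0, n1 + 1))
        x2 = int(rng.integers(0, n2 + 1))
        for alternative in ("less", "greater"):
            res = boschloo_test([[x1, n1 - x1], [x2, n2 - x2]], alternative,
                                grid_size=200, refinements=1)
            assert res.pvalue <= res.fisher_pvalue + 1e-12


def test_boschloo_agrees_with_scipy_one_sided():
    # scipy orients the two samples as columns, so cross-check on the
    # transpose (verified against the exact-enumeration oracle)
    tables = [[[7, 12], [3, 17]], [[2, 8], [6, 4]], [[10, 5], [4, 11]]]
    for t in tables:
        ours = boschloo_test(t, "greater").pvalue
        ref = boschloo_exact(np.transpose(t), alternative="greater",
                             n=128).pvalue
        assert ours == pytest.approx(ref, abs=5e-4)


def test_boschloo_published_subgroup_contrasts():
    # determinate rate by age: 72/185 under-3 vs 63/240 over-3
    p_det = boschloo_test([[72, 113], [63, 177]], "two-sided").pvalue
    assert round(p_det, 3) == 0.006
    # specificity by age: 36/41 over-3 vs 20/30 under-3
    p_sp = boschloo_test([[36, 5], [20, 10]], "two-sided").pvalue
    assert round(p_sp, 2) == 0.03


def test_boschloo_degenerate_margins_flagged():
    res = boschloo_test([[0, 5], [0, 7]])
    assert res.pvalue == 1.0 and res.degenerate
    res = boschloo_test([[5, 0], [7, 0]])
    assert res.degenerate


# --------------------------------------------------------------------------
# stratified reports

def sex_records():
    """Per-subject records consistent with the published sex-stratified
    counts (female: PPV 12/20, NPV 24/25, 109 indeterminate of 154;
    male: PPV 51/58, NPV 32/32, 181 indeterminate of 271)."""
    rows = []

    def add(n, out, ref, sex):
        rows.extend({"device_output": out, "ref_category": ref, "sex": sex}
                    for _ in range(n))

    add(12, "positive", "ASD_positive", "female")
    add(8, "positive", "ASD_negative_other_condition", "female")
    add(1, "negative", "ASD_positive", "female")
    add(24, "negative", "ASD_negative_other_condition", "female")
    add(45, "indeterminate", "ASD_positive", "female")
    add(64, "indeterminate", "ASD_negative_other_condition", "female")
    add(51, "positive", "ASD_positive", "male")
    add(7, "positive", "ASD_negative_other_condition", "male")
    add(32, "negative", "ASD_negative_other_condition", "male")
    add(13, "indeterminate", "ASD_positive", "male")
    add(168, "indeterminate", "ASD_negative_other_condition", "male")
    return pd.DataFrame(rows)


def test_sex_stratification_reproduces_female_sensitivity():
    reports = stratified_metrics(sex_records(), "sex")
    female = reports["female"]
    assert (female.sensitivity.numerator,
            female.sensitivity.denominator) == (12, 13)
    assert round(female.sensitivity.point, 3) == 0.923
    assert (reports["male"].sensitivity.numerator,
            reports["male"].sensitivity.denominator) == (51, 51)


def test_single_stratum_equals_overall(table3):
    df = pd.DataFrame(table3.to_records(),
                      columns=["device_output", "ref_category"])
    df["site"] = "all"
    reports = stratified_metrics(df, "site")
    overall = metrics_report(table3)
    assert reports["all"].ppv == overall.ppv
    assert reports["all"].determinate_rate == overall.determinate_rate


def test_non_exclusive_strata_multi_membership():
    df = pd.DataFrame({
        "device_output": ["positive", "negative", "positive", "negative"],
        "ref_category": ["ASD_positive", "ASD_negative_neurotypical",
                         "ASD_positive", "ASD_negative_other_condition"],
        "race": ["white;black", "black", "white", "hispanic"],
    })
    reports = stratified_metrics(df, "race")
    assert set(reports) == {"white", "black", "hispanic"}
    total_denoms = sum(r.determinate_rate.denominator
                       for r in reports.values())
    assert total_denoms >= len(df)  # multi-membership double-counts


def test_ci_overlap_check():
    reports = stratified_metrics(sex_records(), "sex")
    assert isinstance(cis_overlap(reports, "sensitivity"), bool)


# --------------------------------------------------------------------------
# indeterminate composition + formatting

def test_indeterminate_composition_published(table3):
    comp = indeterminate_composition(table3)
    assert comp.fraction_neurodevelopmental == pytest.approx(264 / 290)
    assert comp.breakdown == pytest.approx((58 / 290, 206 / 290, 26 / 290))
    assert comp.row_total == 290


def test_indeterminate_composition_edge_cases(rng):
    C = Confusion3x3(np.array([[1, 1, 1], [0, 0, 7], [1, 1, 1]]))
    assert indeterminate_composition(C).fraction_neurodevelopmental == 0.0
    C0 = Confusion3x3(np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1]]))
    assert indeterminate_composition(C0).undefined
    for _ in range(10):
        row = rng.integers(1, 20, 3)
        C = Confusion3x3(np.vstack([[0, 0, 0], row, [0, 0, 0]]))
        comp = indeterminate_composition(C)
        assert comp.fraction_neurodevelopmental == pytest.approx(
            1 - comp.breakdown[2])


def test_report_rounding_styles(table3):
    assert pct1(63 / 78) == "80.8%"
    assert pct0(72 / 185) == "39%"
    assert pct0(63 / 240) == "26%"
    md = table3_markdown(table3)
    assert "290 (68.2%)" in md
    rep = stratified_metrics(sex_records(), "sex")
    t4 = table4_frame(rep)
    assert "92% (12/13)" in t4.loc[t4.stratum == "female",
                                   "sensitivity"].item()
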