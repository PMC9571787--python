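"""Kendall tau-b, ICC(2,1), per-grade summaries and cohort simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmorph.errors import UndefinedStatisticError
from graftmorph.validation_stats import (
    REFERENCE_COHORT_SUMMARY,
    icc_absolute,
    icc_from_rating_table,
    kendall_tau_b,
    kendall_tau_b_bruteforce,
    pooled_means_from_group_summary,
    read_rating_table,
    simulate_cohort,
    summarize_by_grade,
)


# -- tau-b -------------------------------------------------------------------

def test_tau_perfect_concordance():
    r = kendall_tau_b([0, 1, 2, 3], [10, 20, 30, 40], n_boot=200, seed=0)
    assert r.tau == pytest.approx(1.0)


def test_tau_antisymmetry():
    g = [1, 1, 2, 2, 3]
    v = [5.0, 7.0, 6.0, 9.0, 12.0]
    a = kendall_tau_b(g, v, n_boot=0).tau
    b = kendall_tau_b(g, [-x for x in v], n_boot=0).tau
    assert a == pytest.approx(-b)


def test_tau_matches_bruteforce_with_ties():
    g = [1, 1, 2, 2, 3]
    v = [5.0, 7.0, 6.0, 9.0, 12.0]
    assert kendall_tau_b(g, v, n_boot=0).tau == pytest.approx(
        kendall_tau_b_bruteforce(g, v), abs=1e-12)


def test_tau_seeded_datasets_match_bruteforce():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(5, 50))
        g = rng.integers(0, 4, size=n)
        v = np.round(rng.normal(size=n), 1)  # rounded -> value ties too
        if np.all(g == g[0]) or np.all(v == v[0]):
            continue
        assert kendall_tau_b(g, v, n_boot=0).tau == pytest.approx(
            kendall_tau_b_bruteforce(g, v), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(0, 3), st.integers(-5, 5)), min_size=4, max_size=25))
def test_tau_bruteforce_property(pairs):
    g = np.array([p[0] for p in pairs], float)
    v = np.array([p[1] for p in pairs], float)
    if np.all(g == g[0]) or np.all(v == v[0]):
        return
    assert kendall_tau_b(g, v, n_boot=0).tau == pytest.approx(
        kendall_tau_b_bruteforce(g, v), abs=1e-12)


def test_tau_constant_grades_undefined():
    with pytest.raises(UndefinedStatisticError):
        kendall_tau_b([2, 2, 2, 2], [1.0, 2.0, 3.0, 4.0], n_boot=0)


def test_tau_bootstrap_ci_contains_estimate_and_is_reproducible():
    rng = np.random.default_rng(5)
    g = rng.integers(0, 4, size=31)
    v = g * 10 + rng.normal(0, 8, size=31)
    a = kendall_tau_b(g, v, n_boot=2000, seed=11)
    b = kendall_tau_b(g, v, n_boot=2000, seed=11)
    assert a.ci_low <= a.tau <= a.ci_high
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)  # bit-identical
    assert a.ci_low > 0  # strongly correlated data


# -- ICC ---------------------------------------------------------------------

def icc2_1_anova_oracle(X):
    """From-scratch two-way ANOVA mean squares, written as explicit loops."""
    n, k = X.shape
    grand = sum(X[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_r = sum(k * (sum(X[i]) / k - grand) ** 2 for i in range(n))
    ss_c = sum(n * (sum(X[i][j] for i in range(n)) / n - grand) ** 2
               for j in range(k))
    ss_t = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = (ss_t - ss_r - ss_c) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def test_icc_identical_raters_is_one():
    col = np.arange(6, dtype=float) * 3 + 10
    res = icc_absolute(np.column_stack([col, col]))
    assert res.icc == pytest.approx(1.0)


def test_icc_matches_anova_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 15))
        k = int(rng.integers(2, 5))
        X = rng.normal(50, 10, size=(n, k)) + rng.normal(0, 5, size=(n, 1))
        assert icc_absolute(X).icc == pytest.approx(
            icc2_1_anova_oracle(X), abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    X = rng.normal(30, 8, size=(9, 3)) + rng.normal(0, 4, size=(9, 1))
    mine = icc_absolute(X)
    df = pd.DataFrame({
        "t": np.repeat(np.arange(9), 3),
        "r": np.tile(np.arange(3), 9),
        "s": X.ravel(),
    })
    ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s"
                             ).set_index("Type").loc["ICC(A,1)"]
    assert mine.icc == pytest.approx(float(ref.ICC), abs=1e-10)
    assert mine.p_value == pytest.approx(float(ref.pval), abs=1e-10)
    assert mine.ci_low == pytest.approx(ref.CI95[0], abs=0.01)
    assert mine.ci_high == pytest.approx(ref.CI95[1], abs=0.01)


def test_icc_systematic_offset_reduces_absolute_agreement():
    col = np.arange(8, dtype=float) * 5 + 20
    perfect = icc_absolute(np.column_stack([col, col])).icc
    offset = icc_absolute(np.column_stack([col, col + 10.0])).icc
    assert offset < perfect == 1.0


def test_icc_zero_between_subject_variance_warns_zero():
    X = np.full((6, 2), 5.0)
    with pytest.warns(UserWarning, match="zero between-subject"):
        res = icc_absolute(X)
    assert res.icc == 0.0


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_absolute(np.zeros((3, 2)))
    bad = np.ones((6, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        icc_absolute(bad)


# -- summaries ---------------------------------------------------------------

def test_pooled_means_reproduce_cohort_totals():
    out = pooled_means_from_group_summary()
    assert round(out["pooled_t0_mm3"]) == 2931
    assert round(out["pooled_followup_mm3"]) == 2010
    assert round(out["pooled_resorption_mm3"]) == 921


def test_summarize_weighted_total_identity():
    table = simulate_cohort(seed=2)
    s = summarize_by_grade(table)
    ns = s.loc[[1, 2, 3], "n"]
    weighted = (s.loc[[1, 2, 3], "mean_t0_mm3"] * ns).sum() / ns.sum()
    assert s.loc["Total", "mean_t0_mm3"] == pytest.approx(weighted)
    assert s.loc["Total", "mean_resorption_pct_signed"] == pytest.approx(
        -s.loc["Total", "mean_resorption_pct"])


def test_summarize_empty_grade_and_single_patient_sd():
    table = pd.DataFrame({
        "patient_id": ["a", "b"],
        "zhu_grade": [1, 2],
        "rater": ["R0", "R0"],
        "session": [0, 0],
        "volume_t0_mm3": [2000.0, 2500.0],
        "volume_followup_mm3": [1800.0, 1500.0],
    })
    s = summarize_by_grade(table)
    assert s.loc[0, "n"] == 0 and np.isnan(s.loc[0, "mean_t0_mm3"])
    assert s.loc[1, "n"] == 1 and np.isnan(s.loc[1, "sd_t0_mm3"])


# -- cohort simulation -------------------------------------------------------

def test_simulated_cohort_matches_strata_sizes():
    t = simulate_cohort(seed=0)
    counts = t.groupby("zhu_grade")["patient_id"].nunique()
    assert counts.to_dict() == {g: REFERENCE_COHORT_SUMMARY[g][0]
                                for g in (1, 2, 3)}


def test_zero_rater_noise_gives_perfect_icc():
    t = simulate_cohort(seed=0, n_raters=2, rater_sigma_mm3=0.0)
    assert icc_from_rating_table(t, by="rater").icc == pytest.approx(1.0)


def test_increasing_rater_noise_decreases_mean_icc():
    means = []
    for sigma in (50.0, 200.0, 600.0):
        vals = [
            icc_from_rating_table(
                simulate_cohort(seed=s, n_raters=2, rater_sigma_mm3=sigma),
                by="rater").icc
            for s in range(15)
        ]
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


def test_rating_table_io_validation(tmp_path):
    t = simulate_cohort(seed=0)
    path = tmp_path / "ratings.csv"
    t.to_csv(path, index=False)
    back = read_rating_table(path)
    assert len(back) == len(t)
    bad = t.copy()
    bad.loc[0, "zhu_grade"] = 7
    bad.to_csv(path, index=False)
    with pytest.raises(ValueError, match="zhu_grade"):
        read_rating_table(path)
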