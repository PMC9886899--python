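"""Contingency tests, ROC/AUC with DeLong intervals, model comparison, and
chained-equation imputation, each checked against an independent oracle."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from sklearn.metrics import roc_auc_score

from glbn import (
    apply_missingness,
    choose_test,
    compare_rocs,
    fisher_exact,
    multiple_impute,
    pearson_chi2,
    relapse_comparison,
    roc_auc,
)
from glbn.schema import SchemaError

TABLE1 = np.array([[289, 614], [277, 433]])


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by rational enumeration (independent route)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    ws = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    num = sum(w for w in ws.values() if w <= ws[a])
    return Fraction(num, sum(ws.values()))


# -- chi-square ---------------------------------------------------------------

def test_duration_comparison_statistic_and_proportions():
    res = pearson_chi2(TABLE1)
    assert res.statistic == pytest.approx(8.5745, abs=5e-4)
    assert res.df == 1
    assert res.p_value == pytest.approx(0.003, abs=5e-4)
    rep = relapse_comparison({6: (289, 614), 12: (277, 433)})
    assert rep["proportions"][6] * 100 == pytest.approx(32.0, abs=0.05)
    assert rep["proportions"][12] * 100 == pytest.approx(39.0, abs=0.05)
    assert rep["test"] == "pearson_chi2"


def test_chi2_identical_rows_is_zero_and_hand_formula():
    assert pearson_chi2([[50, 50], [50, 50]]).statistic == 0.0
    t = np.array([[10, 20], [30, 5]])
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    assert pearson_chi2(t).statistic == pytest.approx(((t - e) ** 2 / e).sum())


def test_chi2_closed_form_2x2_and_permutation_invariance():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.integers(1, 60, size=(2, 2))
        (a, b), (c, d) = t
        n = t.sum()
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert pearson_chi2(t).statistic == pytest.approx(closed)
        assert pearson_chi2(t[::-1]).statistic == pytest.approx(closed)
        assert pearson_chi2(t[:, ::-1]).statistic == pytest.approx(closed)


def test_chi2_zero_marginal_rejected():
    with pytest.raises(SchemaError):
        pearson_chi2([[0, 0], [5, 5]])


# -- Fisher's exact ------------------------------------------------------------

def test_fisher_example_matches_enumeration():
    got = fisher_exact(np.array([[1, 9], [11, 3]])).p_value
    assert got == pytest.approx(float(fisher_oracle(1, 9, 11, 3)), abs=1e-12)
    assert got == pytest.approx(scipy_fisher([[1, 9], [11, 3]])[1], abs=1e-9)


def test_fisher_odds_ratio_one_gives_p_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_requires_2x2():
    with pytest.raises(SchemaError):
        fisher_exact(np.ones((2, 3), dtype=int))


def test_fisher_exhaustive_small_tables():
    """All 2x2 tables with N <= 25 against the rational enumeration oracle."""
    worst = 0.0
    for n in range(1, 26):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            p = fisher_exact(np.array([[a, b], [c, d]])).p_value
            worst = max(worst, abs(p - float(fisher_oracle(a, b, c, d))))
    assert worst < 1e-12


def test_fisher_against_scipy_samples():
    rng = np.random.default_rng(1)
    for _ in range(200):
        t = rng.integers(0, 30, size=(2, 2))
        assert fisher_exact(t).p_value == pytest.approx(
            scipy_fisher(t)[1], abs=1e-9
        )


# -- test selection rule --------------------------------------------------------

def test_choose_test_rule():
    assert choose_test(TABLE1) == "pearson_chi2"
    assert choose_test([[1, 1], [1, 50]]) == "fisher_exact"
    # all expected counts exactly 5: strict "<5" keeps the chi-square
    assert choose_test([[5, 5], [5, 5]]) == "pearson_chi2"
    assert choose_test([[2, 8], [3, 40]]) == "fisher_exact"


# -- ROC / AUC -------------------------------------------------------------------

def test_auc_degenerate_cases():
    y = np.r_[np.ones(10), np.zeros(10)]
    s = np.r_[np.arange(10, 20), np.arange(10)]
    assert roc_auc(y, s).auc == 1.0
    assert roc_auc(y, np.zeros(20)).auc == 0.5


def test_auc_hand_example_with_tie():
    y = np.array([1, 1, 1, 0, 0, 0])
    s = np.array([0.9, 0.7, 0.4, 0.7, 0.3, 0.1])
    pos, neg = s[y == 1], s[y == 0]
    pairs = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg) / 9
    res = roc_auc(y, s)
    assert res.auc == pytest.approx(pairs)
    assert res.auc == pytest.approx(roc_auc_score(y, s))
    assert res.ci[0] <= res.auc <= res.ci[1]
    assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
    assert res.fpr[0] == 0.0 and res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_score_negation_symmetry(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    y = rng.integers(0, 2, n)
    if y.sum() in (0, n):
        y[0], y[-1] = 0, 1
    s = np.round(rng.normal(size=n), 1)
    assert roc_auc(y, s).auc + roc_auc(y, -s).auc == pytest.approx(1.0)


def test_auc_matches_sklearn_on_random_data():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 300)
    s = rng.normal(size=300) + 0.7 * y
    assert roc_auc(y, s).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_compare_rocs_identity_and_errors():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 120)
    s = rng.normal(size=120) + y
    comp = compare_rocs(y, s, s)
    assert comp.auc_difference == 0.0
    with pytest.raises(ValueError):
        compare_rocs(y, s, s[:-1])
    other = rng.normal(size=120)
    boot1 = compare_rocs(y, s, other, bootstrap=50, seed=9)
    boot2 = compare_rocs(y, s, other, bootstrap=50, seed=9)
    assert boot1.bootstrap_ci == boot2.bootstrap_ci
    assert boot1.bootstrap_ci[0] < boot1.bootstrap_ci[1]


def test_delong_interval_width_shrinks_with_n():
    rng = np.random.default_rng(5)
    widths = []
    for n in (100, 1000):
        y = rng.integers(0, 2, n)
        s = rng.normal(size=n) + 0.8 * y
        r = roc_auc(y, s)
        widths.append(r.ci[1] - r.ci[0])
    assert widths[1] < widths[0]


# -- multiple imputation ----------------------------------------------------------

def test_impute_complete_table_returns_copies(small_cohort):
    table, _, _ = small_cohort
    out = multiple_impute(table, m=3, seed=0)
    assert len(out) == 3
    assert all(o.df.equals(table.df) for o in out)


def test_impute_preserves_marginals_and_is_reproducible(small_cohort):
    table, _, _ = small_cohort
    masked = apply_missingness(table, 0.1, seed=2)
    outs = multiple_impute(masked, m=3, seed=5)
    col = "family_relationship"
    for o in outs:
        assert not o.df.drop(columns=["participant_id"]).isna().any().any()
        for lvl in table.spec(col).levels:
            p_full = (table.df[col] == lvl).mean()
            p_imp = (o.df[col] == lvl).mean()
            se = np.sqrt(max(p_full * (1 - p_full), 1e-6) / len(table))
            assert abs(p_imp - p_full) < 4 * se
    outs2 = multiple_impute(masked, m=3, seed=5)
    assert all(a.df.equals(b.df) for a, b in zip(outs, outs2))


def test_impute_rejects_fully_missing_column(small_cohort):
    table, _, _ = small_cohort
    broken = table.copy()
    broken.df["hiv"] = np.nan
    with pytest.raises(SchemaError):
        multiple_impute(broken, m=1, seed=0)
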