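"""Classical statistics around the risk models: contingency-table tests,
ROC/AUC with DeLong confidence intervals, model comparison, and chained-
equation multiple imputation for categorical tables."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .schema import CohortTable, SchemaError


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise SchemaError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise SchemaError("counts must be non-negative")

    @property
    def expected(self) -> np.ndarray:
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        n = self.counts.sum()
        if n == 0 or np.any(r == 0) or np.any(c == 0):
            raise SchemaError("table has a zero marginal")
        return r * c / n


@dataclass
class TestResult:
    test: str  # "pearson_chi2" or "fisher_exact"
    statistic: float | None
    df: int | None
    p_value: float


def pearson_chi2(table: ContingencyTable | np.ndarray) -> TestResult:
    """Uncorrected Pearson chi-square (no Yates continuity correction)."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    e = table.expected  # raises on zero marginals
    stat = float(((table.counts - e) ** 2 / e).sum())
    df = (table.counts.shape[0] - 1) * (table.counts.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult("pearson_chi2", stat, df, p)


def fisher_exact(table: ContingencyTable | np.ndarray) -> TestResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one.  The
    comparison is done on exact integer weights ``C(r1,a) * C(r2, c1-a)``, so
    mathematical ties are handled without floating-point ambiguity.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    if table.counts.shape != (2, 2):
        raise SchemaError(
            "fisher_exact supports 2x2 tables only; collapse sparse levels of "
            "larger tables before testing"
        )
    (a, b), (c, d) = table.counts
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    den = sum(weights)
    return TestResult("fisher_exact", None, None, num / den)


def choose_test(table: ContingencyTable | np.ndarray) -> str:
    """Fisher's exact test when any expected count is <1 or more than 20% of
    cells have expected counts <5; the Pearson chi-square otherwise."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    e = table.expected
    if (e < 1).any() or (e < 5).mean() > 0.2:
        return "fisher_exact"
    return "pearson_chi2"


def relapse_comparison(counts_by_duration: dict[int, tuple[int, int]]) -> dict:
    """Analogue of the duration comparison table: relapse proportions per
    cohort and the appropriate independence test across durations."""
    rows = sorted(counts_by_duration)
    table = np.array([counts_by_duration[d] for d in rows])
    test_name = choose_test(table)
    res = pearson_chi2(table) if test_name == "pearson_chi2" else fisher_exact(table)
    out = {
        "durations": rows,
        "counts": table.tolist(),
        "proportions": {
            d: counts_by_duration[d][0] / sum(counts_by_duration[d]) for d in rows
        },
        "test": res.test,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
    }
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc(labels, scores, alpha: float = 0.05) -> RocResult:
    """AUC via the Mann-Whitney identity (ties count one half) with a DeLong
    confidence interval, plus the ROC curve at every score threshold."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size:
        raise ValueError("labels and scores must have equal length")
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative labels")

    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    # DeLong placements
    all_ranks = ranks
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[y == 1] - pos_ranks) / n0  # P(score_pos > random neg)
    v01 = 1.0 - (all_ranks[y == 0] - neg_ranks) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    var = s10 / n1 + s01 / n0
    z = -ndtri(alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # curve: thresholds descending over unique scores
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    uniq = np.r_[True, np.diff(s[order]) != 0]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    keep = np.r_[np.flatnonzero(np.r_[uniq[1:], True])]
    tpr = np.r_[0.0, tp[keep] / n1]
    fpr = np.r_[0.0, fp[keep] / n0]
    thresholds = np.r_[np.inf, s[order][keep]]
    return RocResult(fpr, tpr, thresholds, float(auc), ci, n1, n0)


def delong_test_variance(labels, scores_a, scores_b) -> float:
    """Variance of the paired AUC difference (DeLong covariance structure)."""
    y = np.asarray(labels, dtype=float).ravel()
    out = []
    for s in (scores_a, scores_b):
        s = np.asarray(s, dtype=float).ravel()
        pos, neg = s[y == 1], s[y == 0]
        ranks = sps.rankdata(s)
        v10 = (ranks[y == 1] - sps.rankdata(pos)) / neg.size
        v01 = 1.0 - (ranks[y == 0] - sps.rankdata(neg)) / pos.size
        out.append((v10, v01))
    (a10, a01), (b10, b01) = out
    n1, n0 = a10.size, a01.size
    s10 = np.cov(a10, b10)[0, 1] if n1 > 1 else 0.0
    s01 = np.cov(a01, b01)[0, 1] if n0 > 1 else 0.0
    va = a10.var(ddof=1) / n1 + a01.var(ddof=1) / n0
    vb = b10.var(ddof=1) / n1 + b01.var(ddof=1) / n0
    cov = s10 / n1 + s01 / n0
    return float(va + vb - 2 * cov)


@dataclass
class ModelComparison:
    roc_a: RocResult
    roc_b: RocResult
    auc_difference: float
    bootstrap_ci: tuple[float, float] | None = None


def compare_rocs(
    labels, scores_a, scores_b, bootstrap: int = 0, seed: int = 0
) -> ModelComparison:
    """Paired in-sample ROC comparison of two score vectors on the same rows."""
    labels = np.asarray(labels, dtype=float).ravel()
    sa = np.asarray(scores_a, dtype=float).ravel()
    sb = np.asarray(scores_b, dtype=float).ravel()
    if not (labels.size == sa.size == sb.size):
        raise ValueError("labels and both score vectors must align row-wise")
    ra, rb = roc_auc(labels, sa), roc_auc(labels, sb)
    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        diffs = np.empty(bootstrap)
        n = labels.size
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            while len(np.unique(labels[idx])) < 2:
                idx = rng.integers(0, n, size=n)
            diffs[b] = (
                roc_auc(labels[idx], sa[idx]).auc - roc_auc(labels[idx], sb[idx]).auc
            )
        ci = (float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975)))
    return ModelComparison(ra, rb, ra.auc - rb.auc, ci)


def compare_models(
    cohort: CohortTable,
    bn_scores: np.ndarray,
    logistic_scores: np.ndarray,
    bootstrap: int = 0,
    seed: int = 0,
) -> ModelComparison:
    """Compare the BN and the group-lasso logistic model on the same rows."""
    y = (cohort.df[cohort.outcome].astype(str) == "yes").to_numpy(dtype=float)
    return compare_rocs(y, bn_scores, logistic_scores, bootstrap=bootstrap, seed=seed)


# ---------------------------------------------------------------------------
# Multiple imputation (chained equations over categorical columns)
# ---------------------------------------------------------------------------

def _impute_chain(
    df: pd.DataFrame, missing: pd.DataFrame, rng: np.random.Generator,
    max_sweeps: int,
) -> pd.DataFrame:
    work = df.copy()
    cols = [c for c in df.columns if missing[c].any()]
    # initialize from observed marginals
    for c in cols:
        obs = df[c].dropna().to_numpy()
        n_miss = int(missing[c].sum())
        work.loc[missing[c], c] = rng.choice(obs, size=n_miss)
    for _ in range(max_sweeps):
        changed = 0
        for c in cols:
            others = [x for x in df.columns if x != c]
            key = pd.Series(
                list(map(tuple, work[others].astype(str).to_numpy())),
                index=work.index,
            )
            obs_mask = ~missing[c]
            freq: dict = {}
            grouped = work.loc[obs_mask, c].groupby(key[obs_mask])
            for k, grp in grouped:
                levels, counts = np.unique(grp.astype(str), return_counts=True)
                freq[k] = (levels, counts / counts.sum())
            marg_levels, marg_counts = np.unique(
                df[c].dropna().astype(str), return_counts=True
            )
            marg = (marg_levels, marg_counts / marg_counts.sum())
            for i in work.index[missing[c]]:
                levels, probs = freq.get(key[i], marg)
                new = rng.choice(levels, p=probs)
                if new != work.at[i, c]:
                    changed += 1
                work.at[i, c] = new
        if changed == 0:
            break
    return work


def multiple_impute(
    table: CohortTable, m: int = 5, max_sweeps: int = 5, seed: int = 0
) -> list[CohortTable]:
    """m completed copies of the table via chained equations.

    Each incomplete column is refilled by multinomial draws from the
    empirical distribution of the column conditional on the current completed
    values of all other columns (falling back to the marginal when a
    configuration was never observed complete), sweeping until the imputed
    cells stabilise or ``max_sweeps`` passes.  Chains are independent and
    seeded, so the result set is reproducible.
    """
    df = table.df
    missing = df.isna()
    fully_missing = [c for c in df.columns if missing[c].all()]
    if fully_missing:
        raise SchemaError(f"column(s) entirely missing: {fully_missing}")
    if not missing.any().any():
        return [table.copy() for _ in range(m)]
    out = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        completed = _impute_chain(df, missing, rng, max_sweeps)
        out.append(CohortTable(completed, table.specs))
    return out
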