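"""Descriptive-comparison tests for the cohort characteristics table.

Fisher's exact test is implemented for general r x c tables because the
3-level HIV variable needs a 2 x 3 test and scipy covers 2 x 2 only.
Small tables are enumerated exhaustively over all tables with the observed
margins; large tables fall back to a Monte-Carlo permutation p-value at a
fixed seed.  The Wilcoxon rank-sum comparison uses the normal
approximation with tie and continuity corrections (the convention of
R's ``wilcox.test``), since NLR values contain ties after rounding.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency, mannwhitneyu

#: relative slack when comparing table probabilities, as in R's fisher.test
_P_TOL = 1e-7


def _log_fact(x):
    return gammaln(np.asarray(x, float) + 1.0)


def _table_log_prob(table, row_m, col_m, n):
    return (_log_fact(row_m).sum() + _log_fact(col_m).sum()
            - _log_fact(n) - _log_fact(table).sum())


def fisher_exact_rxc(table, mc_seed: int = 0, mc_draws: int = 100_000,
                     enumeration_limit: int = 500_000) -> float:
    """Two-sided Fisher exact p-value for an r x c contingency table.

    Sums the hypergeometric probabilities of all margin-preserving tables
    no more probable than the observed one.  If the enumeration would
    visit more than ``enumeration_limit`` tables, a Monte-Carlo
    permutation estimate with ``mc_draws`` draws is returned instead
    (deterministic given ``mc_seed``).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")
    obs_logp = _table_log_prob(table, row_m, col_m, n)
    r, c = table.shape

    total = 0.0
    visited = 0
    overflow = False

    def recurse(i, j, current, row_rem, col_rem):
        nonlocal total, visited, overflow
        if overflow:
            return
        if j == c - 1:  # last cell of the row is forced
            v = row_rem
            if v > col_rem[j]:
                return
            current[i, j] = v
            col_rem[j] -= v
            if i == r - 2:
                # last row forced entirely by the column margins
                current[r - 1, :] = col_rem
                visited += 1
                if visited > enumeration_limit:
                    overflow = True
                else:
                    lp = _table_log_prob(current, row_m, col_m, n)
                    if lp <= obs_logp + _P_TOL:
                        total += np.exp(lp)
            else:
                recurse(i + 1, 0, current, int(row_m[i + 1]), col_rem)
            col_rem[j] += v
            return
        hi = min(row_rem, int(col_rem[j]))
        for v in range(hi + 1):
            current[i, j] = v
            col_rem[j] -= v
            recurse(i, j + 1, current, row_rem - v, col_rem)
            col_rem[j] += v
            if overflow:
                return

    if r >= 2:
        recurse(0, 0, np.zeros_like(table), int(row_m[0]), col_m.astype(int).copy())
    if not overflow:
        return float(min(total, 1.0))

    # Monte-Carlo permutation fallback
    rng = np.random.default_rng(mc_seed)
    rows = np.repeat(np.arange(r), row_m)
    cols = np.repeat(np.arange(c), col_m)
    hits = 0
    for _ in range(mc_draws):
        perm = rng.permutation(cols)
        sim = np.bincount(rows * c + perm, minlength=r * c).reshape(r, c)
        if _table_log_prob(sim, row_m, col_m, n) <= obs_logp + _P_TOL:
            hits += 1
    return float((hits + 1) / (mc_draws + 1))


def chi_square_p(table) -> float:
    """Pearson chi-square p-value (Yates continuity correction for 2 x 2)."""
    table = np.asarray(table, float)
    _, p, _, _ = chi2_contingency(table, correction=(table.shape == (2, 2)))
    return float(p)


def expected_counts(table) -> np.ndarray:
    table = np.asarray(table, float)
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie and
    continuity corrected)."""
    res = mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                       alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return float(res.pvalue)
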