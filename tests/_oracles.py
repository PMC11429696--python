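"""Independent brute-force oracles used to pin expected values in tests.

These deliberately avoid the library code paths they check: rank-test null
distributions are enumerated exhaustively, regressions are solved through the
normal equations, and t/correlation statistics are assembled from their
textbook formulas.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy import stats


def exact_signed_rank_p(diffs) -> float:
    """Two-sided signed-rank p by enumeration of all 2^n sign assignments.

    Requires nonzero, tie-free |differences| (the regime where the exact null
    is defined). p = 2 * min(P(T+ <= t), P(T+ >= t)), capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    assert (d != 0).all() and np.unique(np.abs(d)).size == d.size
    ranks = stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = d.size
    stats_all = [np.asarray(signs) @ ranks for signs in product([0, 1], repeat=n)]
    stats_all = np.asarray(stats_all)
    p_low = np.mean(stats_all <= t_obs + 1e-9)
    p_high = np.mean(stats_all >= t_obs - 1e-9)
    return min(1.0, 2.0 * min(p_low, p_high))


def exact_rank_sum_p(g1, g2) -> float:
    """Two-sided rank-sum p by enumeration of all rank assignments (no ties)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    pooled = np.concatenate([g1, g2])
    assert np.unique(pooled).size == pooled.size
    ranks = stats.rankdata(pooled)
    n1 = g1.size
    t_obs = ranks[:n1].sum()
    all_ranks = np.arange(1, pooled.size + 1)
    sums = np.asarray([sum(c) for c in combinations(all_ranks, n1)], dtype=float)
    p_low = np.mean(sums <= t_obs + 1e-9)
    p_high = np.mean(sums >= t_obs - 1e-9)
    return min(1.0, 2.0 * min(p_low, p_high))


def ols_normal_equations(X, y):
    """Solve OLS coefficients through the normal equations X'X b = X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def partial_r_by_residuals(x, y, c) -> float:
    """Partial correlation by two explicit simple regressions on the control."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    def resid(v):
        slope = np.cov(v, c, ddof=1)[0, 1] / np.var(c, ddof=1)
        intercept = v.mean() - slope * c.mean()
        return v - intercept - slope * c
    rx, ry = resid(x), resid(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def one_sample_t_vs_half(vals) -> tuple[float, float]:
    """(t, two-sided p) of a textbook one-sample t test against 0.5."""
    v = np.asarray(vals, dtype=float)
    n = v.size
    m = v.mean()
    sd = v.std(ddof=1)
    t = (m - 0.5) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def pearson_with_fisher_ci(x, y) -> tuple[float, float, tuple[float, float]]:
    """(r, two-sided p, Fisher 95% CI) assembled from the textbook formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    r = float(np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1)))
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return r, p, (float(np.tanh(z - half)), float(np.tanh(z + half)))
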