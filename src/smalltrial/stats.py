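"""Test statistics shared by the trial simulators.

Everything here is vectorised over a leading replicate axis so operating
characteristics can be computed for thousands of simulated trials in one
call.  Degenerate inputs (an empty arm, a pooled proportion of 0 or 1) give a
p-value of 1 rather than an error: the simulators decide which replicates
count as non-informative.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_combine",
    "fisher_combine_rows",
    "two_proportion_pvalue",
    "welch_pvalue",
    "savage_pvalue",
    "ls_slopes",
]


def fisher_combine(p_values) -> float:
    """Combine independent p-values with Fisher's method.

    The statistic is ``X = -2 * sum(log p_i)``; the combined p-value is the
    upper tail of a chi-square distribution with ``2k`` degrees of freedom at
    ``X``.  Each p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("at least one p-value is required")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError(f"p-values must lie in (0, 1]: {p}")
    stat = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(stat, 2 * p.size))


def fisher_combine_rows(p_matrix: np.ndarray) -> np.ndarray:
    """Row-wise Fisher combination (replicates x k p-values)."""
    p = np.asarray(p_matrix, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum(axis=-1)
    return sps.chi2.sf(stat, 2 * p.shape[-1])


def two_proportion_pvalue(x1, n1, x2, n2, alternative: str = "two-sided") -> np.ndarray:
    """Pooled-variance two-proportion z-test (score test), elementwise.

    ``alternative='greater'`` tests p1 > p2.  Replicates with an empty arm or
    a degenerate pooled proportion return p = 1.
    """
    x1, n1, x2, n2 = (np.asarray(a, dtype=float) for a in (x1, n1, x2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (x1 / n1 - x2 / n2) / se
    ok = (n1 > 0) & (n2 > 0) & np.isfinite(z)
    z = np.where(ok, z, 0.0)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(np.abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.where(ok, p, 1.0)


def welch_pvalue(
    mean1, var1, n1, mean2, var2, n2, alternative: str = "two-sided"
) -> np.ndarray:
    """Welch two-sample t-test from summary statistics, elementwise.

    ``var*`` are sample variances (ddof=1). ``alternative='less'`` tests
    mean1 < mean2.
    """
    mean1, var1, mean2, var2 = (
        np.asarray(a, dtype=float) for a in (mean1, var1, mean2, var2)
    )
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v1, v2 = var1 / n1, var2 / n2
        se2 = v1 + v2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1 - 1.0) + v2**2 / (n2 - 1.0))
    ok = (n1 > 1) & (n2 > 1) & np.isfinite(t) & np.isfinite(df)
    t = np.where(ok, t, 0.0)
    df = np.where(ok, df, 1.0)
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(np.abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.where(ok, p, 1.0)


def savage_pvalue(times_a: np.ndarray, times_b: np.ndarray) -> np.ndarray:
    """Two-sample exponential-scores (Savage) rank test, two-sided, per row.

    Equivalent to the log-rank test when there is no censoring; the natural
    comparison for exponential-like response latencies.  Inputs are
    (replicates, n_a) and (replicates, n_b) arrays of positive times.
    """
    times_a = np.atleast_2d(times_a)
    times_b = np.atleast_2d(times_b)
    na, nb = times_a.shape[1], times_b.shape[1]
    n = na + nb
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([times_a, times_b], axis=1)
    order = np.argsort(combined, axis=1, kind="stable")
    # Savage score of rank r (0-indexed): sum_{j<=r} 1/(n-j) - 1; scores sum to 0.
    scores = np.cumsum(1.0 / (n - np.arange(n))) - 1.0
    s = np.empty_like(combined)
    rows = np.arange(combined.shape[0])[:, None]
    s[rows, order] = scores
    w = s[:, :na].sum(axis=1)
    var = na * nb / (n * (n - 1.0)) * np.sum(scores**2)
    z = w / np.sqrt(var)
    return 2.0 * sps.norm.sf(np.abs(z))


def ls_slopes(scores: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Per-series least-squares slope over the last axis.

    ``scores`` has shape (..., n_visits); ``times`` is the common visit grid.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two visit times for a slope")
    w = t - t.mean()
    return np.asarray(scores, dtype=float) @ (w / np.sum(w**2))
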