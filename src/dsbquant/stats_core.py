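"""Inferential utilities shared across the pipeline.

Unpaired Welch t-test (unequal variances, Welch-Satterthwaite degrees of
freedom), two-sided Mann-Whitney U with an exact small-sample branch, the
standard error of the mean, and the usual asterisk notation for p-values.
All tests are two-sided.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "welch_t",
    "welch_t_arrays",
    "mann_whitney_u",
    "sem",
    "significance_stars",
]

# product of group sizes below which the exact U distribution is enumerated
EXACT_U_LIMIT = 400


def welch_t_arrays(mx, vx, nx, my, vy, ny):
    """Vectorised Welch test from group means, sample variances and sizes.

    Returns ``(t, df, p)`` arrays.  Rows where both variances are zero are
    degenerate: p is 1 when the means agree and 0 in the limiting unequal-mean
    case (df is set to the pooled ``nx + ny - 2`` there).
    """
    mx, vx, my, vy = (np.asarray(a, dtype=float) for a in (mx, vx, my, vy))
    sx = vx / nx
    sy = vy / ny
    denom = sx + sy
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(denom)
        df = denom**2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    p = 2.0 * stats.t.sf(np.abs(t), np.where(degenerate, 1.0, df))
    if np.any(degenerate):
        equal = degenerate & (mx == my)
        t = np.where(equal, 0.0, t)
        t = np.where(degenerate & ~equal, np.where(mx > my, np.inf, -np.inf), t)
        df = np.where(degenerate, nx + ny - 2.0, df)
        p = np.where(equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)
    return t, df, p


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sample unequal-variance t-test.

    Parameters are two samples of at least two observations each.  Returns
    ``(t_stat, df, p_value)`` with the Welch-Satterthwaite df and a two-sided
    p from the t distribution.  If both samples have zero variance the result
    is degenerate and a RuntimeWarning is emitted (p = 1 for equal means,
    p = 0 for the unequal-mean limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        warnings.warn(
            "degenerate Welch test: zero variance in both groups",
            RuntimeWarning,
            stacklevel=2,
        )
    t, df, p = welch_t_arrays(x.mean(), vx, x.size, y.mean(), vy, y.size)
    return float(t), float(df), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` with U for group x.

    The exact null distribution is used when the sample-size product is at
    most 400 and the pooled data carry no ties; otherwise the normal
    approximation with midranks and tie-corrected variance applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u needs non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and x.size * y.size <= EXACT_U_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sem(x) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("sem needs at least 2 observations")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def significance_stars(p: float) -> str:
    """Asterisk label for a p-value: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"
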