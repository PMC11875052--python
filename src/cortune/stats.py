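"""Multiple-testing and paired-test primitives shared across the pipeline.

The Benjamini-Hochberg step-up procedure is implemented here directly (it is
applied per neuron to small families of tests throughout the tuning
analysis); paired t tests go through scipy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

__all__ = ["benjamini_hochberg", "paired_ttest_pvalues"]


def benjamini_hochberg(pvalues, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Rejects hypotheses 1..k* in sorted order, where k* is the largest k with
    ``p_(k) <= k * q / m``.  Returns ``(reject, p_adjusted)`` in the original
    order; adjusted p-values are monotone nondecreasing in sorted order and
    clipped to 1.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
    q : false discovery rate, in (0, 1]
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")

    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)

    # step-up: largest k with p_(k) <= k q / m rejects everything at or below
    below = p_sorted <= ranks * q / m
    reject_sorted = np.zeros(m, dtype=bool)
    if below.any():
        k_star = np.max(np.nonzero(below)[0])
        reject_sorted[: k_star + 1] = True

    adj_sorted = np.minimum.accumulate((p_sorted * m / ranks)[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)

    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m, dtype=float)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def paired_ttest_pvalues(
    x: np.ndarray, y: np.ndarray, axis: int = -1, alternative: str = "two-sided"
) -> np.ndarray:
    """Paired t test p-values along ``axis``; NaN where differences are constant.

    A zero-variance difference vector carries no evidence either way, so the
    corresponding p-value is NaN (never counted as a rejection) unless the
    constant difference is nonzero, in which case p is 0 for a consistent
    alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have identical shape")
    d = x - y
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sstats.ttest_rel(x, y, axis=axis, alternative=alternative)
        p = np.asarray(res.pvalue, dtype=float)
    # scipy yields NaN for zero-variance differences; keep NaN when the
    # constant difference is 0, call a consistent nonzero difference exact.
    dm = d.mean(axis=axis)
    dv = d.var(axis=axis)
    const = dv == 0
    if np.ndim(p) == 0:
        if const and dm != 0:
            sign_ok = (
                alternative == "two-sided"
                or (alternative == "greater" and dm > 0)
                or (alternative == "less" and dm < 0)
            )
            p = 0.0 if sign_ok else 1.0
        return np.asarray(p, dtype=float)
    exact = const & (dm != 0)
    if alternative == "greater":
        p[exact] = np.where(dm[exact] > 0, 0.0, 1.0)
    elif alternative == "less":
        p[exact] = np.where(dm[exact] < 0, 0.0, 1.0)
    else:
        p[exact] = 0.0
    return p
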