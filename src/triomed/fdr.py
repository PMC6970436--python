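"""Genome-wide FDR control across unique gene pairs.

Per-trio permutation p-values handle the many correlated variants tested per
(cis gene, trans gene) pair; the Storey-Tibshirani q-value procedure then
controls the FDR across the genome-wide collection of unique gene pairs.
Benjamini-Hochberg adjustment is also exposed (used for the cis-association
FDR column when building candidate trios, and as the q-value fallback).
"""
from __future__ import annotations

import warnings

import numpy as np
from statsmodels.stats.multitest import multipletests

#: default discovery thresholds: suggestive permutation p, significant q
SUGGESTIVE_P = 0.05
SIGNIFICANT_FDR = 0.25


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoothed estimate of the true-null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on the grid
    0.05, 0.10, ..., 0.95 and smoothed with a cubic spline; the estimate is
    the smoothed value at the largest lambda, clipped to (0, 1].  With fewer
    than 100 p-values (or a non-positive spline value) the conservative
    fallback min(1, 2 * mean(p)) is used instead.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    fallback = min(1.0, 2.0 * float(p.mean()))
    if m < 100:
        warnings.warn("too few p-values for spline pi0; using 2*mean(p) fallback")
        return max(fallback, 1.0 / m)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    from scipy.interpolate import UnivariateSpline

    spline = UnivariateSpline(lambdas, pi0_lam, k=3)
    pi0 = float(spline(lambdas[-1]))
    if pi0 <= 0:
        warnings.warn("spline pi0 non-positive; using 2*mean(p) fallback")
        return max(fallback, 1.0 / m)
    return min(pi0, 1.0)


def storey_tibshirani_qvalues(
    p: np.ndarray, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values and the pi0 estimate used.

    q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank(p_j); q-values are
    monotone non-decreasing in p and invariant to input order.  Forcing
    pi0 = 1 reproduces Benjamini-Hochberg exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)
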