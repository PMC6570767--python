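"""Shared statistical primitives used across the pipeline.

A single Mann–Whitney U code path serves the cluster contrast comparisons and
the motility condition comparisons.  For small samples the two-sided p-value
is computed by exhaustive enumeration of all group assignments of the pooled
observations (exact under ties); for larger samples the tie-corrected normal
approximation is used, matching common statistical practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: both groups at or below this size use the exact permutation distribution
EXACT_MAX_N = 10


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    median_a: float
    median_b: float
    method: str  # "exact" or "asymptotic"
    degenerate: bool = False  # all pooled values identical


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j, ties count 1/2."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test between two samples.

    Exact enumeration when both groups have ≤ ``EXACT_MAX_N`` observations,
    otherwise tie-corrected normal approximation (no continuity correction in
    the exact path; the asymptotic path applies the standard 0.5 correction).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(
            u=a.size * b.size / 2.0, p=1.0, median_a=med_a, median_b=med_b,
            method="exact", degenerate=True,
        )
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # enumerate all C(n1+n2, n1) assignments of pooled values to group A;
        # two-sided p = share of assignments at least as far from the mean U
        total = comb(n1 + n2, n1)
        idx_all = np.fromiter(
            (i for c in combinations(range(n1 + n2), n1) for i in c),
            dtype=np.intp, count=total * n1,
        ).reshape(total, n1)
        mask = np.zeros((total, n1 + n2), dtype=bool)
        np.put_along_axis(mask, idx_all, True, axis=1)
        # U via rank-sum: U = R1 - n1(n1+1)/2, with midranks for ties
        ranks = stats.rankdata(pooled)
        r1 = np.where(mask, ranks[None, :], 0.0).sum(axis=1)
        u_all = r1 - n1 * (n1 + 1) / 2.0
        extreme = np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-12
        p = float(extreme.sum() / total)
        return MannWhitneyResult(u_obs, p, med_a, med_b, "exact")
    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (np.abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u_obs, min(p, 1.0), med_a, med_b, "asymptotic")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TTestResult:
    mean: float
    t: float | None
    p: float | None
    n: int
    degenerate: bool  # zero variance or n < 2: no p-value reported


def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test with explicit degenerate-case reporting.

    Zero-variance samples (or n < 2) are flagged instead of yielding p = 0 or
    NaN, so callers can exclude them from downstream summaries.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    mean = float(np.mean(x)) if n else float("nan")
    if n < 2 or np.ptp(x) == 0.0:
        return TTestResult(mean=mean, t=None, p=None, n=n, degenerate=True)
    t, p = stats.ttest_1samp(x, popmean)
    return TTestResult(mean=mean, t=float(t), p=float(p), n=n, degenerate=False)


def spearman(x, y) -> float | None:
    """Spearman rank correlation with midrank ties; None when undefined.

    Returns ``None`` when either input is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have matching shape")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
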