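"""Independent brute-force oracles used to verify the statistical primitives.

Each oracle recomputes its statistic from first principles (exhaustive
enumeration, direct tail summation, explicit midranks) without touching the
package's implementation path.
"""

from itertools import combinations
from math import comb

import numpy as np


def permutation_mann_whitney_p(a, b) -> float:
    """Exhaustive two-sided permutation p for the Mann–Whitney U statistic.

    Enumerates every assignment of the pooled values into groups of sizes
    (|a|, |b|); U is counted directly from pairwise comparisons (ties 1/2);
    two-sided tail by distance of U from its permutation mean.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0

    def u_of(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_of(a, b)
    count = 0
    total = comb(n1 + n2, n1)
    idx = set(range(n1 + n2))
    for grp in combinations(range(n1 + n2), n1):
        x = pooled[list(grp)]
        y = pooled[list(idx - set(grp))]
        if abs(u_of(x, y) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def hypergeom_tail_p(k, K, n, N) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact integer summation."""
    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def midrank_spearman(x, y) -> float:
    """Spearman rho via explicitly computed midranks and the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def bh_stepup(p) -> np.ndarray:
    """Hand application of the Benjamini–Hochberg step-up rule."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
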