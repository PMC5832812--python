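"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (enumeration, normal equations,
explicit minimisation) and shares no code with the package.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_enumeration(table):
    """Two-sided Fisher P by full hypergeometric enumeration.

    Sums point probabilities of all 2x2 tables with the observed margins
    whose probability is <= that of the observed table (minimum-likelihood
    convention). Returns (p, numerator, denominator) as exact integers
    scaled by the common denominator C(n, r1).
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d

    def weight(k):  # numerator of P(X=k), common denominator C(n, r1)
        return comb(c1, k) * comb(n - c1, r1 - k)

    obs = weight(a)
    num = sum(w for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
              if (w := weight(k)) <= obs)
    den = comb(n, r1)
    return num / den, num, den


def wilcoxon_two_sided_enumeration(x, y):
    """Exact two-sided rank-sum P by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    m, n = len(x), len(pooled)
    mean = m * (n + 1) / 2
    stats = [sum(i + 1 for i in idx) for idx in combinations(range(n), m)]
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)


def simes_bruteforce(pvals):
    """Explicit minimisation over all (m, P(m)) pairs of the ordered list."""
    ordered = sorted(pvals)
    n = len(ordered)
    best = 1.0
    for m, p in enumerate(ordered, start=1):
        best = min(best, n * p / m)
    return min(best, 1.0)


def bh_stepup_by_hand(pvals):
    """Textbook Benjamini-Hochberg step-up with running-minimum from the top."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def ols_normal_equations(x_cols, y):
    """Least squares via explicit normal equations; returns (coefs, rss, df)."""
    X = np.column_stack([np.ones(len(y)), *x_cols])
    XtX = X.T @ X
    coefs = np.linalg.solve(XtX, X.T @ np.asarray(y, dtype=float))
    resid = y - X @ coefs
    return coefs, float(resid @ resid), len(y) - X.shape[1]
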