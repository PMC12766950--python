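"""Independent brute-force oracles used to pin the package's statistics.

Each oracle enumerates the relevant null distribution (or runs the naive
running sum) in a deliberately different way from the implementation, so a
shared bug cannot hide.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import rankdata


def ranksum_exact_oracle(x, y, alternative: str) -> float:
    """Enumerate every assignment of pooled ranks to the x-group."""
    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    ge = le = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def signed_rank_exact_oracle(x, mu0: float, alternative: str) -> float:
    """Enumerate all 2^n sign vectors of the nonzero differences."""
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = total = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def fisher_2x2_oracle(table, alternative: str) -> Fraction:
    """Exact-rational hypergeometric tail over the support of the top-left cell."""
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    denom = comb(n, row1)
    pmf = {k: Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for k, p in pmf.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in pmf.items() if k <= a)
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def fisher_rxc_oracle(table) -> float:
    """Two-sided exact p by exhaustive product-enumeration of cell values."""
    arr = np.asarray(table, dtype=int)
    r, c = arr.shape
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    n = arr.sum()

    def logprob(t):
        from scipy.special import gammaln

        t = np.asarray(t)
        return float(
            gammaln(row_sums + 1).sum()
            + gammaln(col_sums + 1).sum()
            - gammaln(n + 1)
            - gammaln(t + 1).sum()
        )

    lp_obs = logprob(arr)
    ranges = [range(min(row_sums[i], col_sums[j]) + 1) for i in range(r) for j in range(c)]
    p = 0.0
    for flat in itertools.product(*ranges):
        t = np.array(flat).reshape(r, c)
        if (t.sum(axis=1) == row_sums).all() and (t.sum(axis=0) == col_sums).all():
            lp = logprob(t)
            if lp <= lp_obs + 1e-9:
                p += np.exp(lp)
    return min(p, 1.0)


def spearman_exact_oracle(x, y) -> tuple[float, float]:
    """rho plus the two-sided p from enumerating all orderings of y."""
    rx = rankdata(np.asarray(x, dtype=float))
    ry = rankdata(np.asarray(y, dtype=float))
    n = rx.size

    def rho_of(perm):
        r = ry[list(perm)]
        return float(np.corrcoef(rx, r)[0, 1])

    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(rho_of(perm)) >= abs(rho_obs) - 1e-9:
            count += 1
    return rho_obs, count / total


def bh_oracle(pvals) -> np.ndarray:
    """Naive sorted-formula Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def ssgsea_oracle(profile_values, profile_genes, members, weight=1.0):
    """Naive running-sum ES: explicit loop over the ranked gene list."""
    order = sorted(range(len(profile_genes)), key=lambda i: (-profile_values[i], profile_genes[i]))
    hits = [profile_genes[i] in members for i in order]
    vals = [abs(profile_values[i]) ** weight for i in order]
    n = len(order)
    nh = sum(hits)
    if nh == n:
        return 1.0
    if nh == 0:
        return 0.0
    denom = sum(v for v, h in zip(vals, hits) if h)
    running = 0.0
    best = 0.0
    for v, h in zip(vals, hits):
        if h:
            running += (v / denom) if denom > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best
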