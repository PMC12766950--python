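"""Nonparametric and exact statistics used throughout the pipeline.

Every test is implemented from first principles so its small-sample null can be
computed by exact enumeration; the large-sample defaults deliberately mirror
the tie-uncorrected, continuity-uncorrected normal approximations of the usual
scientific-Python routines so that results line up with common practice:

* :func:`spearman` — rank correlation with average ranks for ties; exact
  permutation p for n <= 10, t-approximation above.
* :func:`rank_sum_test` — two-sample Wilcoxon rank-sum / Mann-Whitney; normal
  approximation on the rank sum by default, full enumeration on request.
* :func:`signed_rank_one_sample` — one-sample Wilcoxon signed-rank against a
  hypothesised location; exact sign-assignment null for n <= 20.
* :func:`fisher_exact_2x2` / :func:`fisher_exact_rxc` — hypergeometric exact
  tests, with Monte-Carlo fallback over fixed-margin tables for large r x c.
* :func:`adjust_pvalues` — Bonferroni and Benjamini-Hochberg corrections.
* :func:`qpcr_expression_score` — the 40 - dCT transform used for qPCR panels.

All p-values are strictly positive; Monte-Carlo p-values use the add-one
correction (k+1)/(n+1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "UndefinedStatisticError",
    "spearman",
    "rank_sum_test",
    "signed_rank_one_sample",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "adjust_pvalues",
    "qpcr_expression_score",
]

Alternative = Literal["greater", "less", "two_sided"]
_EPS = 1e-12


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. correlation of a constant)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: Alternative
    method: str
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _validate_alternative(alternative: str) -> Alternative:
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return alternative  # type: ignore[return-value]


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Spearman correlation


def _perm_chunks(n: int, chunk: int = 100_000):
    """Yield (m, n) integer arrays covering all permutations of range(n)."""
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            return
        yield np.array(block, dtype=np.int8)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact p by enumerating all n! orderings of the y-ranks.

    With marginal rank vectors fixed, rho is an affine function of the sum of
    products, so the tail condition |rho_perm| >= |rho_obs| reduces to a
    condition on the dot product.
    """
    n = rx.size
    sp_obs = float(rx @ ry)
    center = n * rx.mean() * ry.mean()
    dev_obs = abs(sp_obs - center)
    count = 0
    total = math.factorial(n)
    for block in _perm_chunks(n):
        # each row of `block` is an ordering of positions for the y-ranks
        perm_sums = ry[block] @ rx
        count += int(np.sum(np.abs(perm_sums - center) >= dev_obs - 1e-9))
    return count / total


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks. For n <= 10 the p-value comes from exact
    enumeration of all rank permutations (tie multiplicity ignored in the
    null, a documented simplification); above that the usual t-approximation
    with n-2 degrees of freedom is used. A constant input raises
    :class:`UndefinedStatisticError` rather than propagating NaN.
    """
    xa = _as_vector(x, "x")
    ya = _as_vector(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rx = rankdata(xa)
    ry = rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman-exact"
    else:
        p = _spearman_t_p(rho, n)
        method = "spearman-t"
    return TestResult(statistic=rho, p_value=max(p, _EPS), alternative="two_sided", method=method)


def _spearman_t_p(rho: float, n: int) -> float:
    """Two-sided t-approximation p for a Spearman rho (vector-safe)."""
    denom = np.maximum(1.0 - np.square(rho), _EPS)
    t = rho * np.sqrt((n - 2) / denom)
    return 2.0 * t_dist.sf(np.abs(t), df=n - 2)


# ---------------------------------------------------------------------------
# rank-sum (Mann-Whitney / Wilcoxon two-sample)

_MAX_EXACT_COMB = 3_000_000


def rank_sum_test(
    x,
    y,
    alternative: Alternative = "two_sided",
    exact: bool = False,
) -> TestResult:
    """Wilcoxon rank-sum test on two independent samples.

    The default is the tie-uncorrected normal approximation on the rank sum of
    ``x`` with no continuity correction (the convention of the standard
    ``ranksums`` routine). ``exact=True`` enumerates all assignments of the
    pooled ranks to the two groups (feasible for small samples).
    """
    alternative = _validate_alternative(alternative)
    xa = _as_vector(x, "x")
    ya = _as_vector(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    if exact:
        n = n1 + n2
        ncomb = math.comb(n, n1)
        if ncomb > _MAX_EXACT_COMB:
            raise ValueError("sample too large for exact enumeration")
        sums = np.fromiter(
            (ranks[list(c)].sum() for c in itertools.combinations(range(n), n1)),
            dtype=float,
            count=ncomb,
        )
        p_greater = np.mean(sums >= w - 1e-9)
        p_less = np.mean(sums <= w + 1e-9)
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return TestResult(statistic=w, p_value=max(float(p), 1.0 / ncomb), alternative=alternative, method="rank-sum-exact")
    mean = n1 * (n1 + n2 + 1) / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - mean) / sd
    if alternative == "greater":
        p = norm.sf(z)
    elif alternative == "less":
        p = norm.cdf(z)
    else:
        p = 2.0 * norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(max(min(p, 1.0), _EPS)), alternative=alternative, method="rank-sum-normal")


# ---------------------------------------------------------------------------
# one-sample signed-rank


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of W+ (in half-rank units) over all 2^n sign assignments."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_one_sample(
    x,
    mu0: float = 0.0,
    alternative: Alternative = "two_sided",
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of location against ``mu0``.

    Differences exactly equal to ``mu0`` are dropped (Wilcoxon convention);
    at least 5 nonzero differences are required. The null is exact for
    n <= 20 (all sign assignments, via the subset-sum distribution of W+)
    and a tie-uncorrected normal approximation beyond.
    """
    alternative = _validate_alternative(alternative)
    xa = _as_vector(x, "x")
    d = xa - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all observations equal mu0")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 20:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        dist = _signed_rank_distribution(ranks2)
        total = 2.0**n
        p_greater = dist[w2:].sum() / total
        p_less = dist[: w2 + 1].sum() / total
        method = "signed-rank-exact"
    else:
        mean = n * (n + 1) / 4.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (w_plus - mean) / sd
        p_greater = norm.sf(z)
        p_less = norm.cdf(z)
        method = "signed-rank-normal"
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(statistic=w_plus, p_value=float(max(p, _EPS)), alternative=alternative, method=method)


# ---------------------------------------------------------------------------
# Fisher exact tests


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if not np.issubdtype(arr.dtype, np.integer):
        as_int = np.round(arr).astype(np.int64)
        if not np.array_equal(as_int, arr):
            raise ValueError("contingency table must contain integers")
        arr = as_int
    if np.any(arr < 0):
        raise ValueError("contingency table entries must be non-negative")
    return arr.astype(np.int64)


def fisher_exact_2x2(table, alternative: Alternative = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table with the sample odds ratio.

    The odds ratio is the cross-product (ad)/(bc); infinity is reported when
    bc = 0 (and NaN when both products vanish). ``greater`` tests whether the
    top-left cell is larger than expected under fixed margins.
    """
    alternative = _validate_alternative(alternative)
    arr = _check_table(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if b * c == 0:
        oddsratio = math.inf if a * d > 0 else math.nan
    else:
        oddsratio = (a * d) / (b * c)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(col1, ks)
        + _log_comb(n - col1, row1 - ks)
        - _log_comb(n, row1)
    )
    pmf = np.exp(logpmf)
    pmf = pmf / pmf.sum()
    p_obs = pmf[ks == a][0]
    if alternative == "greater":
        p = pmf[ks >= a].sum()
    elif alternative == "less":
        p = pmf[ks <= a].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
    return TestResult(
        statistic=float(a),
        p_value=float(max(min(p, 1.0), _EPS)),
        alternative=alternative,
        method="fisher-2x2",
        effect_size=oddsratio,
    )


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _table_logprob(arr: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray, n: int) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(arr + 1).sum()
    )


def _enumerate_tables(row_sums: Sequence[int], col_sums: Sequence[int]):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row: int, remaining_cols: tuple[int, ...], built: list[list[int]]):
        if row == r - 1:
            last = list(remaining_cols)
            if all(v >= 0 for v in last) and sum(last) == row_sums[row]:
                yield np.array(built + [last], dtype=np.int64)
            return
        target = row_sums[row]

        def fill(col: int, left: int, current: list[int]):
            if col == c - 1:
                if 0 <= left <= remaining_cols[col]:
                    yield current + [left]
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                yield from fill(col + 1, left - v, current + [v])

        for row_vals in fill(0, target, []):
            new_remaining = tuple(rc - v for rc, v in zip(remaining_cols, row_vals))
            yield from rec(row + 1, new_remaining, built + [row_vals])

    yield from rec(0, tuple(col_sums), [])


_EXACT_RXC_MAX_N = 40
_EXACT_RXC_MAX_SHAPE = (3, 5)


def fisher_exact_rxc(
    table,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Two-sided Fisher exact test on an r x c table.

    Rows/columns that are entirely zero are dropped with a warning. Small
    tables (total count <= 40, shape within 3 x 5 in either orientation) are
    solved by full enumeration of fixed-margin tables; larger ones by
    Monte-Carlo sampling of fixed-margin tables with the add-one corrected
    p-value (k+1)/(n_mc+1).
    """
    arr = _check_table(table)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("table must be at least 2x2")
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from contingency table")
        arr = arr[keep_rows][:, keep_cols]
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("table degenerate after dropping empty margins")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    n = int(arr.sum())
    logp_obs = _table_logprob(arr, row_sums, col_sums, n)
    shape = tuple(sorted(arr.shape))
    small = n <= _EXACT_RXC_MAX_N and shape[0] <= _EXACT_RXC_MAX_SHAPE[0] and shape[1] <= _EXACT_RXC_MAX_SHAPE[1]
    if small:
        p = 0.0
        for tab in _enumerate_tables(row_sums.tolist(), col_sums.tolist()):
            lp = _table_logprob(tab, row_sums, col_sums, n)
            if lp <= logp_obs + 1e-9:
                p += math.exp(lp)
        method = "fisher-rxc-exact"
        p = min(p, 1.0)
    else:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(arr.shape[1]), col_sums)
        row_edges = np.cumsum(row_sums)[:-1]
        k = 0
        for _ in range(n_mc):
            rng.shuffle(labels)
            parts = np.split(labels, row_edges)
            tab = np.stack(
                [np.bincount(part, minlength=arr.shape[1]) for part in parts]
            )
            if _table_logprob(tab, row_sums, col_sums, n) <= logp_obs + 1e-9:
                k += 1
        p = (k + 1) / (n_mc + 1)
        method = "fisher-rxc-mc"
    return TestResult(
        statistic=float(math.exp(logp_obs)),
        p_value=float(max(p, _EPS)),
        alternative="two_sided",
        method=method,
    )


# ---------------------------------------------------------------------------
# multiple-testing correction


def adjust_pvalues(pvals, method: Literal["bonferroni", "bh"] = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# qPCR


def qpcr_expression_score(ct_target: float, ct_reference: float) -> float:
    """Relative expression on the 40 - dCT scale used for qPCR panels.

    Higher values mean more abundant transcript; equality of target and
    reference cycles gives the scale maximum of 40.
    """
    for name, ct in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not (0.0 < ct <= 40.0):
            raise ValueError(f"{name}={ct} outside (0, 40]")
    return 40.0 - (ct_target - ct_reference)
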