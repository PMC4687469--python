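"""Rank statistics used by the methylation analysis.

Both statistics are implemented here in full (average-rank tie handling,
exact small-sample enumeration for the U test) so their behaviour at the
cohort sizes involved — 19 correlation pairs, 22-vs-24 group comparison —
is explicit and testable against independent references.
"""
from __future__ import annotations

from itertools import combinations
from math import comb, erfc, sqrt
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DataValueError, InsufficientDataError


class CorrelationResult(NamedTuple):
    rho: float
    p_two_sided: float
    n: int


class UTestResult(NamedTuple):
    u: float
    p_two_sided: float
    method: str  # "exact" or "normal"


def _rankdata(values: Sequence[float]) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mean of 1-based ranks i+1..j
        i = j
    return ranks


def spearman_rho(
    x: Sequence[float], y: Sequence[float], exact_p: bool = False
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the tie-averaged rank vectors. The
    p-value uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2
    degrees of freedom; with ``exact_p`` (n <= 10) it is computed instead by
    full permutation enumeration of one rank vector.
    """
    if len(x) != len(y):
        raise DataValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    rx, ry = _rankdata(x), _rankdata(y)
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0.0 or sy == 0.0:
        raise DataValueError("correlation undefined for a constant vector")
    rho = float(np.mean((rx - np.mean(rx)) * (ry - np.mean(ry))) / (sx * sy))

    if exact_p:
        if n > 10:
            raise DataValueError("exact permutation p limited to n <= 10")
        from itertools import permutations

        count = 0
        total = 0
        cx = rx - np.mean(rx)
        for perm in permutations(range(n)):
            r = float(np.mean(cx * (ry[list(perm)] - np.mean(ry))) / (sx * sy))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return CorrelationResult(rho, count / total, n)

    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n)
    t = rho * sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, min(p, 1.0), n)


def _u_from_ranks(a: Sequence[float], b: Sequence[float]) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = _rankdata(pooled)
    n_a = len(a)
    u_a = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2.0)
    return u_a, pooled


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with average-rank ties. The p-value is
    exact (enumeration of all rank assignments) when the pooled sample has
    at most 12 observations and no ties; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    """
    if len(a) == 0 or len(b) == 0:
        raise DataValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u_a, pooled = _u_from_ranks(a, b)
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n_a + n_b <= 12 and not has_ties:
        # enumerate every way the a-group ranks could fall in the pooled order
        n = n_a + n_b
        count = 0
        total = comb(n, n_a)
        for positions in combinations(range(1, n + 1), n_a):
            u_perm = sum(positions) - n_a * (n_a + 1) / 2.0
            if min(u_perm, n_a * n_b - u_perm) <= u + 1e-9:
                count += 1
        return UTestResult(u, count / total, "exact")

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 == 0.0:
        return UTestResult(u, 1.0, "normal")
    z = (abs(u - mu) - 0.5) / sqrt(sigma2)  # continuity correction
    z = max(z, 0.0)
    p = erfc(z / sqrt(2.0))
    return UTestResult(u, min(p, 1.0), "normal")
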