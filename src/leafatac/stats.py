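"""Shared statistical primitives: hypergeometric tails, rank tests, BH.

These are thin, convention-pinning wrappers: every enrichment p-value in the
package flows through :func:`hypergeom_tail` (one-sided, over-representation)
and every two-group expression comparison through :func:`rank_test`.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

from .errors import ContractError


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the one-sided Fisher p-value.

    N = universe size, K = annotated ("white") elements, n = drawn set size,
    k = observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ContractError(f"invalid hypergeometric table N={N} K={K} n={n}")
    if k <= max(0, n + K - N):
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_2x2_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for table [[a, b], [c, d]].

    Rows: in-set / not-in-set; columns: in-term / not-in-term.  Identical to
    the hypergeometric upper tail with N=a+b+c+d, K=a+c, n=a+b, k=a.
    """
    return hypergeom_tail(a, a + b + c + d, a + c, a + b)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x over y, counting ties as 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_test(x, y, method: str = "auto") -> float:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) p-value.

    For small samples (len(x) + len(y) <= 12) the exact null distribution of
    U is obtained by exhaustive enumeration over all labelings of the combined
    sample, which handles ties without approximation; otherwise a normal
    approximation with tie correction and continuity correction is used.
    ``method`` may force "exact" or "asymptotic".

    The two-sided exact p is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("rank_test requires at least 2 values per group")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= 12 else "asymptotic"
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    if method == "exact":
        return _rank_test_exact(x, y)
    if method == "asymptotic":
        return _rank_test_asymptotic(x, y)
    raise ValueError(f"unknown method {method!r}")


def _rank_test_exact(x: np.ndarray, y: np.ndarray) -> float:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    u_obs = _mann_whitney_u(x, y)
    total = math.comb(n + m, n)
    le = ge = 0
    idx = np.arange(n + m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        u = _mann_whitney_u(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)


def _rank_test_asymptotic(x: np.ndarray, y: np.ndarray) -> float:
    n, m = len(x), len(y)
    N = n + m
    u = _mann_whitney_u(x, y)
    mu = n * m / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def pearson_r(x, y) -> float:
    """Pearson correlation; raises on zero variance rather than returning NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ContractError("pearson_r needs two equal-length vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("pearson_r undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])
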