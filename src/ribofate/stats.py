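"""Statistical primitives: multiplicity corrections, one-sided Fisher's exact
test, and Kruskal-Wallis with Dunn's post hoc test (tie-corrected, two-sided
normal approximation, as in the FSA reference implementation)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .core import RibofateError


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    method: str


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment: q_i = min_{j>=i} p_(j) * n / j, capped at 1,
    mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise RibofateError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bonferroni(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise RibofateError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def adjust(p_values, method: str) -> np.ndarray:
    if method == "benjamini_hochberg":
        return benjamini_hochberg(p_values)
    if method == "bonferroni":
        return bonferroni(p_values)
    raise RibofateError(f"unknown correction method {method!r}")


def fisher_exact_onesided(
    k: int, n: int, K: int, N: int
) -> tuple[float, float]:
    """Upper-tail Fisher exact test for over-representation.

    ``k`` targets observed in a group of ``n`` draws from a universe of ``N``
    genes of which ``K`` are targets.  Returns (p, odds_ratio); p is the
    hypergeometric tail P(X >= k).  The odds ratio uses a 0.5 continuity
    correction only when a cell of the 2x2 table is zero (reported, never
    used in the p-value).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise RibofateError(
            f"inconsistent margins: k={k}, n={n}, K={K}, N={N}"
        )
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return min(p, 1.0), odds_ratio


def kruskal_dunn(
    groups: dict[str, "np.ndarray | list[float]"],
    correction: str = "bonferroni",
) -> list[PairwiseTestResult]:
    """Dunn's post hoc test over all group pairs.

    Pooled mid-ranks; z = (Rbar_a - Rbar_b) / sqrt(V * (1/n_a + 1/n_b)) with
    tie-corrected variance V = N(N+1)/12 - sum(t^3 - t) / (12(N-1)); two-sided
    normal p; the chosen correction applied over all pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise RibofateError("need at least two groups")
    sizes = {g: len(np.asarray(groups[g], dtype=float)) for g in labels}
    if any(s == 0 for s in sizes.values()):
        raise RibofateError("empty group")
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in labels:
        n = sizes[g]
        mean_rank[g] = float(ranks[i : i + n].mean())
        i += n
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if N > 1:
        variance = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    else:
        variance = 0.0

    zs, ps, pairs = [], [], []
    for a, b in combinations(labels, 2):
        denom = np.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if denom == 0:  # all pooled values identical
            z = 0.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / denom
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
        pairs.append((a, b))
    p_adj = adjust(ps, correction)
    return [
        PairwiseTestResult(a, b, float(z), float(p), float(q), correction)
        for (a, b), z, p, q in zip(pairs, zs, ps, p_adj)
    ]
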