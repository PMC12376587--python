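"""Rank statistics shared across the pipeline: two-sided Mann-Whitney U
(exact by enumeration for small samples, tie-corrected normal otherwise)
and Benjamini-Hochberg step-up adjustment."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

# exact enumeration cutoff: the smaller sample has at most this many points
EXACT_N_MAX = 8


def mannwhitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the statistic of the first sample. The exact
    branch enumerates all pooled rank assignments (valid under ties); the
    asymptotic branch uses the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    if min(n1, n2) <= EXACT_N_MAX:
        p = _exact_two_sided_p(a, b, u_obs)
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """p = 2 * min(P(U <= u_obs), P(U >= u_obs)) over all C(n1+n2, n1)
    assignments of the pooled values, capped at 1 (handles ties exactly)."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = a.size
    n_le = n_ge = total = 0
    idx_all = frozenset(range(n))
    for group_a in combinations(range(n), n1):
        xa = pooled[list(group_a)]
        xb = pooled[list(idx_all - set(group_a))]
        u = _u_statistic(xa, xb)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(1.0, p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
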