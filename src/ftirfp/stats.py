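"""Exact small-sample inferential statistics.

At n = 5 per group, asymptotic approximations are inappropriate, so the
two-group comparisons are computed exactly:

* Mann–Whitney U with 0.5 per tied pair, and a two-sided p-value obtained by
  enumerating every C(n₁+n₂, n₁) assignment of the pooled observed values
  (which handles ties without a correction formula),
* rank-biserial correlation r = 1 − 2U/(n₁n₂) as the effect size,
* Fisher's exact 2×2 test with two-sidedness by the point-probability rule,
* Pearson chi-square 2×2 without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2, hypergeom

__all__ = [
    "MWUResult",
    "mann_whitney_u",
    "exact_mwu_p",
    "mwu_exact",
    "rank_biserial",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "ENUMERATION_LIMIT",
]

ENUMERATION_LIMIT = 20  # max pooled sample size for exhaustive enumeration


@dataclass(frozen=True)
class MWUResult:
    """Mann–Whitney comparison of two samples (first sample's U)."""

    u: float
    p_two_sided: float
    r_rank_biserial: float
    n1: int
    n2: int
    method: str = "enumeration"


def mann_whitney_u(a, b) -> float:
    """U statistic of sample ``a`` over ``b``: Σ [aᵢ > bⱼ] + 0.5·[aᵢ = bⱼ]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _u_distribution(pooled: np.ndarray, n1: int) -> tuple[np.ndarray, int]:
    """All U values over every assignment of ``pooled`` into groups of n1/rest."""
    n = pooled.size
    # pairwise win matrix: g[i, j] = 1 if pooled[i] > pooled[j], 0.5 if tied
    g = (pooled[:, None] > pooled[None, :]).astype(float)
    g += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(g, 0.0)
    row_tot = g.sum(axis=1)
    us = np.empty(comb(n, n1))
    for k, idx in enumerate(combinations(range(n), n1)):
        sel = list(idx)
        # U(S) = sum over i in S of wins against the complement
        us[k] = row_tot[sel].sum() - g[np.ix_(sel, sel)].sum()
    return us, comb(n, n1)


def exact_mwu_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumeration of the observed values.

    p = min(1, 2·min(P(U ≤ u_obs), P(U ≥ u_obs))) over all group
    reassignments of the pooled data; ties are handled by the enumeration
    itself. Pooled sizes above ``ENUMERATION_LIMIT`` are rejected (a normal
    approximation is out of scope for this pipeline).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 + n2 > ENUMERATION_LIMIT:
        raise ValueError(
            f"pooled size {n1 + n2} exceeds the enumeration bound "
            f"{ENUMERATION_LIMIT}; use a large-sample approximation instead"
        )
    u_obs = mann_whitney_u(a, b)
    us, total = _u_distribution(np.concatenate([a, b]), n1)
    eps = 1e-9
    lo = int(np.sum(us <= u_obs + eps))
    hi = int(np.sum(us >= u_obs - eps))
    return min(1.0, 2.0 * min(lo, hi) / total)


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 − 2U/(n₁n₂)."""
    if not (0 <= u <= n1 * n2):
        raise ValueError(f"U = {u} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * u / (n1 * n2)


def mwu_exact(a, b) -> MWUResult:
    """U, exact two-sided p, and rank-biserial r for two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = mann_whitney_u(a, b)
    return MWUResult(
        u=u,
        p_two_sided=exact_mwu_p(a, b),
        r_rank_biserial=rank_biserial(u, a.size, b.size),
        n1=a.size,
        n2=b.size,
    )


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (point-probability rule).

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed table's
    (with 1e-12 slack for floating-point comparisons).
    """
    t = _as_2x2(table)
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    rv = hypergeom(n, r1, c1)  # X = count in cell (0, 0)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t[0, 0])
    return float(min(1.0, pmf[pmf <= p_obs + 1e-12].sum()))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its 1-df p-value."""
    t = _as_2x2(table).astype(float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))
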