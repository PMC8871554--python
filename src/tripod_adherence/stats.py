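"""Descriptive corpus summaries and exact two-sample rank tests.

Adherence scores are discrete rationals with small denominators (at most the
number of applicable checklist components), so tied scores across studies
are the norm.  The Mann-Whitney U test here therefore treats ties as a
first-class case: without ties the exact null distribution of U comes from
the classical counting recurrence (the Gaussian-binomial generating
function, exact integer arithmetic); with ties, the complete permutation
distribution is enumerated when the number of label assignments is small
enough, otherwise a tie-corrected normal approximation with continuity
correction is used and the method is recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .ratings import StudyRecord
from .scoring import Corpus

__all__ = [
    "CorpusSummary",
    "RankTestResult",
    "GroupComparison",
    "summarize",
    "mann_whitney_exact",
    "u_null_distribution",
    "compare_groups",
]

#: Enumerate the full permutation distribution in the tied case only while
#: C(n1+n2, n1) stays below this; beyond it fall back to the tie-corrected
#: normal approximation.
TIE_ENUMERATION_BOUND = 500_000


@dataclass(frozen=True)
class CorpusSummary:
    """Median, range, threshold proportions and ECDF of a score sample."""

    n: int
    median: Fraction
    min: Fraction
    max: Fraction
    proportion_ge_50: Fraction
    proportion_ge_75: Fraction
    ecdf_points: tuple[tuple[Fraction, Fraction], ...]


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact_enumeration" or "normal_approx_ties"


@dataclass(frozen=True)
class GroupComparison:
    test: RankTestResult
    summary_in: CorpusSummary
    summary_out: CorpusSummary


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(10**12)


def summarize(scores: Sequence) -> CorpusSummary:
    """Describe a sample of scores in [0, 1] with exact arithmetic.

    Median by the midpoint rule; threshold proportions (share of scores at
    or above 1/2 and 3/4) and ECDF breakpoints as exact fractions.  The
    ECDF is the list of (unique score, cumulative fraction) pairs; its last
    cumulative fraction is always 1.
    """
    if len(scores) == 0:
        raise ValueError("summarize requires at least one score")
    vals = sorted(_as_fraction(s) for s in scores)
    n = len(vals)
    if n % 2:
        median = vals[n // 2]
    else:
        median = (vals[n // 2 - 1] + vals[n // 2]) / 2
    ecdf: list[tuple[Fraction, Fraction]] = []
    for i, v in enumerate(vals):
        if i + 1 == n or vals[i + 1] != v:
            ecdf.append((v, Fraction(i + 1, n)))
    return CorpusSummary(
        n=n,
        median=median,
        min=vals[0],
        max=vals[-1],
        proportion_ge_50=Fraction(sum(v >= Fraction(1, 2) for v in vals), n),
        proportion_ge_75=Fraction(sum(v >= Fraction(3, 4) for v in vals), n),
        ecdf_points=tuple(ecdf),
    )


@lru_cache(maxsize=128)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Exact counts of arrangements per U value, u = 0 .. n1*n2, no ties.

    Builds the Gaussian binomial coefficient [n1+n2, n1]_q by alternately
    multiplying by (1 - q^(n2+j)) and dividing by (1 - q^j); all integer,
    so the counts are exact and sum to C(n1+n2, n1).
    """
    max_u = n1 * n2
    c = [0] * (max_u + n1 + 1)
    c[0] = 1
    for j in range(1, n1 + 1):
        shift = n2 + j
        for u in range(len(c) - 1, shift - 1, -1):
            c[u] -= c[u - shift]
        for u in range(j, len(c)):
            c[u] += c[u - j]
    return tuple(c[: max_u + 1])


def u_null_distribution(n1: int, n2: int) -> dict[int, Fraction]:
    """Exact null distribution of U for untied samples, as P(U = u)."""
    counts = _u_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    return {u: Fraction(k, total) for u, k in enumerate(counts)}


def _u_from_ranks(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2)


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    *,
    two_sided: str = "point_probability",
    tie_enumeration_bound: int = TIE_ENUMERATION_BOUND,
) -> RankTestResult:
    """Two-sided Mann-Whitney U test with an exact null where feasible.

    U is computed from midranks of the pooled sample (U of the first
    sample).  The two-sided p-value sums null probabilities of outcomes at
    least as extreme as observed in the sense |U - n1*n2/2| >= observed
    (``two_sided="point_probability"``); ``two_sided="tail_doubling"``
    instead doubles the smaller tail (capped at 1).  Without ties both
    definitions coincide because the null distribution of U is symmetric.
    """
    if two_sided not in ("point_probability", "tail_doubling"):
        raise ValueError(f"unknown two_sided rule {two_sided!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1], n1)
    expected = n1 * n2 / 2
    has_ties = len(np.unique(pooled)) < n1 + n2

    if not has_ties:
        counts = _u_counts(n1, n2)
        total = math.comb(n1 + n2, n1)
        u_int = int(round(u_obs))
        if two_sided == "point_probability":
            d = abs(2 * u_int - n1 * n2)  # 2*|U - E[U]|, integer-exact
            num = sum(
                k for u, k in enumerate(counts) if abs(2 * u - n1 * n2) >= d
            )
        else:
            lo = sum(counts[: u_int + 1])
            hi = sum(counts[u_int:])
            num = min(total, 2 * min(lo, hi))
        return RankTestResult(
            u_statistic=u_obs,
            n1=n1,
            n2=n2,
            p_two_sided=float(Fraction(num, total)),
            method="exact_enumeration",
        )

    n_assign = math.comb(n1 + n2, n1)
    if n_assign <= tie_enumeration_bound:
        base = n1 * (n1 + 1) / 2
        us = np.fromiter(
            (ranks[list(idx)].sum() - base for idx in combinations(range(n1 + n2), n1)),
            dtype=float,
            count=n_assign,
        )
        tol = 1e-9
        if two_sided == "point_probability":
            p = float(
                np.mean(np.abs(us - expected) >= abs(u_obs - expected) - tol)
            )
        else:
            lo = float(np.mean(us <= u_obs + tol))
            hi = float(np.mean(us >= u_obs - tol))
            p = min(1.0, 2 * min(lo, hi))
        return RankTestResult(
            u_statistic=u_obs,
            n1=n1,
            n2=n2,
            p_two_sided=p,
            method="exact_enumeration",
        )

    # tie-corrected normal approximation with continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        p = 1.0
    else:
        z = (abs(u_obs - expected) - 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2 * sps.norm.sf(max(z, 0.0)))
    return RankTestResult(
        u_statistic=u_obs,
        n1=n1,
        n2=n2,
        p_two_sided=float(p),
        method="normal_approx_ties",
    )


def compare_groups(
    corpus: Corpus,
    grouping: Callable[[StudyRecord], bool],
    **test_kwargs,
) -> GroupComparison:
    """Rank-test the adherence scores of the studies selected by a predicate
    against the rest of the corpus, with per-group summaries.
    """
    scores_in = [res.score for res, st in corpus if grouping(st)]
    scores_out = [res.score for res, st in corpus if not grouping(st)]
    name = getattr(grouping, "__name__", repr(grouping))
    if not scores_in:
        raise ValueError(f"grouping {name} selects no studies")
    if not scores_out:
        raise ValueError(f"grouping {name} selects every study")
    test = mann_whitney_exact(
        [float(s) for s in scores_in], [float(s) for s in scores_out], **test_kwargs
    )
    return GroupComparison(
        test=test,
        summary_in=summarize(scores_in),
        summary_out=summarize(scores_out),
    )
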