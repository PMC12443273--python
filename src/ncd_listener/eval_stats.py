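"""Evaluation statistics toolkit.

Three instruments used to evaluate dashboard communication and summary
preference studies:

* **A-priori power analysis** for the two-independent-sample t-test under
  the noncentral t distribution. With effect size d (Cohen), group sizes
  n1, n2, the noncentrality parameter is delta = d * sqrt(n1*n2/(n1+n2)),
  df = n1+n2-2, and achieved power is the rejection mass of the noncentral
  t beyond the central-t critical value. ``required_sample_size`` returns
  the smallest group size meeting a target power.
* **Mann-Whitney U test** with midranks, per-group mean ranks, tie-corrected
  normal approximation for large samples and exact permutation enumeration
  for small ones.
* **Likert interpretation**: mean 1-5 ratings are rounded to 2 decimals and
  mapped to five qualitative bins (4.21-5.00 Very Good, 3.41-4.20 Good,
  2.61-3.40 Moderate, 1.81-2.60 Poor, 1.00-1.80 Very Poor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PowerAnalysisSpec",
    "PowerAnalysisResult",
    "RankTestResult",
    "LIKERT_BINS",
    "noncentrality",
    "critical_t",
    "achieved_power",
    "required_sample_size",
    "mann_whitney_u",
    "interpret_likert",
]

ONE = "one"
TWO = "two"

# Above this many pairwise comparisons the exact permutation null is replaced
# by the tie-corrected normal approximation.
EXACT_ENUMERATION_LIMIT = 64


@dataclass(frozen=True)
class PowerAnalysisSpec:
    """Inputs of an a-priori two-sample t-test power analysis."""

    effect_size_d: float
    alpha: float = 0.05
    target_power: float = 0.80
    tails: str = TWO
    allocation_ratio: float = 1.0  # n2 / n1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.tails not in (ONE, TWO):
            raise ValueError("tails must be 'one' or 'two'")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation_ratio must be positive")


@dataclass(frozen=True)
class PowerAnalysisResult:
    n1: int
    n2: int
    df: int
    noncentrality_delta: float
    critical_t: float
    achieved_power: float


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    mean_rank_1: float
    mean_rank_2: float
    z: float
    p_value: float
    tie_correction_applied: bool
    exact: bool


def noncentrality(d: float, n1: int, n2: int) -> float:
    """Noncentrality parameter delta = d * sqrt(n1*n2 / (n1+n2))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    return d * math.sqrt(n1 * n2 / (n1 + n2))


def critical_t(alpha: float, df: int, tails: str = TWO) -> float:
    """Upper critical value of the central t distribution.

    One-tailed: the upper alpha quantile; two-tailed: the upper alpha/2
    quantile.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    tail_alpha = alpha if tails == ONE else alpha / 2
    return float(stats.t.ppf(1 - tail_alpha, df))


def achieved_power(spec: PowerAnalysisSpec, n1: int, n2: int) -> float:
    """Power of the two-sample t-test at the spec's effect size and alpha.

    One-tailed: P(T' >= t_crit) for T' noncentral t with df = n1+n2-2 and
    delta = noncentrality(d, n1, n2). Two-tailed adds the lower-tail
    rejection mass P(T' <= -t_crit).
    """
    df = n1 + n2 - 2
    delta = noncentrality(spec.effect_size_d, n1, n2)
    tcrit = critical_t(spec.alpha, df, spec.tails)
    power = 1.0 - float(stats.nct.cdf(tcrit, df, delta))
    if spec.tails == TWO:
        power += float(stats.nct.cdf(-tcrit, df, delta))
    return power


def required_sample_size(spec: PowerAnalysisSpec, max_n: int = 1_000_000) -> PowerAnalysisResult:
    """Smallest n1 (n2 = ceil(ratio * n1)) whose achieved power meets target.

    Raises if the effect size is zero (power can never exceed alpha) or the
    search cap is reached.
    """
    if spec.effect_size_d == 0:
        raise ValueError("target power is unreachable with a zero effect size")
    n1 = 2
    while n1 <= max_n:
        n2 = max(2, math.ceil(spec.allocation_ratio * n1))
        power = achieved_power(spec, n1, n2)
        if power >= spec.target_power:
            return PowerAnalysisResult(
                n1=n1,
                n2=n2,
                df=n1 + n2 - 2,
                noncentrality_delta=noncentrality(spec.effect_size_d, n1, n2),
                critical_t=critical_t(spec.alpha, n1 + n2 - 2, spec.tails),
                achieved_power=power,
            )
        n1 += 1
    raise ValueError(f"no group size up to {max_n} reaches the target power")


def _u_statistic(group1: Sequence[float], group2: Sequence[float]) -> float:
    """U for group 1: the count of (x, y) pairs with x > y, ties counting 1/2."""
    u = 0.0
    for x in group1:
        for y in group2:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_u(
    group1: Sequence[float], group2: Sequence[float], tails: str = TWO
) -> RankTestResult:
    """Mann-Whitney U test with midranks and per-group mean ranks.

    For n1*n2 <= 64 the p-value is computed by exhaustive enumeration of all
    group-1 index subsets of the pooled sample (exact, tie-aware); larger
    problems use the normal approximation with tie-corrected variance and a
    0.5 continuity correction. All values identical across both groups give
    p = 1 with the tie flag set.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    if tails not in (ONE, TWO):
        raise ValueError("tails must be 'one' or 'two'")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)  # midranks
    mean_rank_1 = float(ranks[:n1].mean())
    mean_rank_2 = float(ranks[n1:].mean())
    u = _u_statistic(g1, g2)

    ties = np.unique(pooled, return_counts=True)[1]
    has_ties = bool((ties > 1).any())

    if np.all(pooled == pooled[0]):
        return RankTestResult(u, mean_rank_1, mean_rank_2, 0.0, 1.0, True, True)

    mu = n1 * n2 / 2.0
    if n1 * n2 <= EXACT_ENUMERATION_LIMIT:
        # exact permutation null of U over all assignments of pooled values
        null: list[float] = []
        idx = range(n1 + n2)
        for subset in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(subset)] = True
            null.append(_u_statistic(pooled[mask], pooled[~mask]))
        null_arr = np.asarray(null)
        if tails == TWO:
            p = float(np.mean(np.abs(null_arr - mu) >= abs(u - mu) - 1e-12))
        else:
            p = float(np.mean(null_arr >= u - 1e-12))
        z = (u - mu) / null_arr.std() if null_arr.std() > 0 else 0.0
        return RankTestResult(u, mean_rank_1, mean_rank_2, float(z), p, has_ties, True)

    n = n1 + n2
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    # continuity correction toward the mean
    if tails == TWO:
        z = (u - mu - 0.5 * np.sign(u - mu)) / sigma if u != mu else 0.0
        p = 2 * float(stats.norm.sf(abs(z)))
    else:
        z = (u - mu - 0.5) / sigma
        p = float(stats.norm.sf(z))
    return RankTestResult(u, mean_rank_1, mean_rank_2, float(z), min(p, 1.0), has_ties, False)


LIKERT_BINS: tuple[tuple[float, float, str], ...] = (
    (1.00, 1.80, "Very Poor"),
    (1.81, 2.60, "Poor"),
    (2.61, 3.40, "Moderate"),
    (3.41, 4.20, "Good"),
    (4.21, 5.00, "Very Good"),
)


def interpret_likert(mean_score: float) -> str:
    """Map a mean 1-5 rating to its qualitative label.

    The score is first rounded half-up to 2 decimals (so 4.205 -> 4.21 ->
    Very Good); scores outside [1.00, 5.00] are rejected.
    """
    rounded = float(
        Decimal(repr(float(mean_score))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    if rounded < 1.00 or rounded > 5.00:
        raise ValueError(f"mean score {mean_score} outside the 1-5 Likert range")
    for lower, upper, label in LIKERT_BINS:
        if lower <= rounded <= upper:
            return label
    raise AssertionError("unreachable: bins cover [1.00, 5.00]")  # pragma: no cover
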