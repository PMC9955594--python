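"""Simultaneous-decision baselines: weighted majority votes and voter counts.

When opinions are independent (everyone votes their primary choice at
once), the optimal aggregation is a weighted majority with weights
proportional to each voter's log-odds ratio; with equal weights the
accuracy of a majority of n voters is the binomial tail, which the
Condorcet jury theorem drives to 1 as n grows.  The *effective number of
voters* links the two worlds: the smallest simultaneous committee whose
majority accuracy reaches the limiting performance bound pi_max of an
infinitely long equal-ability sequential chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.optimize import bisect
from scipy.stats import binom

from .chain import AbilityProfile, log_odds
from .closed_forms import pi_max

logger = logging.getLogger("castvote")

#: Brute-force bipartition check cap (2^N subsets).
MAX_BRUTE_FORCE_N = 20

_EXPERT_LABELS = ("expert_1", "expert_2", "expert_3")


@dataclass(frozen=True)
class WeightVector:
    """Normalised non-negative vote weights, one per respondent."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "weights", weights)
        if len(weights) < 1:
            raise ValueError("need at least one weight")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {sum(weights)!r}")

    @classmethod
    def from_raw(cls, raw) -> "WeightVector":
        total = float(sum(raw))
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        return cls(tuple(w / total for w in raw))

    @classmethod
    def log_odds_weights(cls, profile: AbilityProfile) -> "WeightVector":
        """Weights proportional to each respondent's log-odds ratio."""
        return cls.from_raw(profile.log_odds_ratios)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class SimplexRegion:
    """Region of the three-voter weight simplex a profile falls in.

    ``expert_k`` means voter k's log-odds ratio exceeds the sum of the
    other two, so any optimal weighting gives them an outright majority
    (w_k > 0.5, the expert rule); ``majority_interior`` means no single
    voter dominates.
    """

    label: str
    inequality: str

    def __post_init__(self) -> None:
        if self.label not in _EXPERT_LABELS + ("majority_interior",):
            raise ValueError(f"unknown region label {self.label!r}")


def is_optimal_weighting(
    profile: AbilityProfile, weights: WeightVector, tol: float = 1e-12
) -> bool:
    """Whether a weighting always lets the weighted majority pick the likelier option.

    Brute force over all bipartitions (S, T) of the voters: whenever S wins
    the weighted vote, the odds product over S must exceed that over T (and
    symmetrically).  Log-odds-proportional weights satisfy this for every
    profile; equal weights fail once abilities are spread enough.
    """
    n = len(profile)
    if len(weights) != n:
        raise ValueError("weights and profile must have equal length")
    if n > MAX_BRUTE_FORCE_N:
        raise ValueError(f"brute-force check capped at N = {MAX_BRUTE_FORCE_N}")
    r = profile.log_odds_ratios
    w = weights.weights
    for mask in range(2**n):
        w_s = r_s = 0.0
        w_t = r_t = 0.0
        for i in range(n):
            if mask >> i & 1:
                w_s += w[i]
                r_s += r[i]
            else:
                w_t += w[i]
                r_t += r[i]
        if w_s > w_t + tol and r_s <= r_t + tol:
            return False
    return True


def classify_weight_region(
    p1: float, p2: float, p3: float, tol: float = 1e-9
) -> SimplexRegion:
    """Classify a three-voter ability triple into its optimum-weight region."""
    r = [log_odds(p) for p in (p1, p2, p3)]
    for p in (p1, p2, p3):
        if not 0.5 < p < 1.0:
            raise ValueError(f"abilities must lie in (0.5, 1); got {p!r}")
    for k in range(3):
        rest = sum(r) - r[k]
        if abs(r[k] - rest) <= tol:
            logger.warning(
                "ability triple sits on an expert-rule boundary (r*_%d ~ sum of "
                "the others); classifying as majority_interior",
                k + 1,
            )
            return SimplexRegion(
                "majority_interior", f"r*_{k + 1} = r* of the others (boundary tie)"
            )
    for k in range(3):
        rest = sum(r) - r[k]
        if r[k] > rest:
            return SimplexRegion(
                _EXPERT_LABELS[k], f"r*_{k + 1} > sum of the other log-odds"
            )
    return SimplexRegion(
        "majority_interior", "every r*_k below the sum of the other two"
    )


def majority_accuracy(p: float, n: int) -> float:
    """Accuracy of a simple majority of n independent voters of ability p.

    The binomial tail ``sum_{m >= (n+1)/2} C(n, m) p^m (1-p)^(n-m)``;
    requires odd n so no tie-break is needed.  Equals p at n = 1 and, for
    p > 0.5, increases to 1 with n (Condorcet jury theorem).
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"n must be a positive odd integer, got {n}")
    if not 0.5 < p < 1.0:
        raise ValueError(f"ability must lie in (0.5, 1); got {p!r}")
    return float(binom.sf((n - 1) // 2, n, p))


def effective_voters(p: float, n_max: int = 201) -> int:
    """Effective number of simultaneous voters matching a sequential chain.

    Smallest odd n whose simple-majority accuracy reaches ``pi_max(p)``,
    the limiting mean performance of an infinite equal-ability sequential
    chain.  (The defining equality generically has no integer solution, so
    the first odd n attaining the bound is reported.)
    """
    target = pi_max(p)
    for n in range(1, n_max + 1, 2):
        if majority_accuracy(p, n) >= target:
            return n
    raise ValueError(
        f"majority accuracy did not reach pi_max({p}) = {target} by n = {n_max}"
    )


def crossing_ability(
    n: int = 5, xtol: float = 1e-10, bracket_margin: float = 1e-6
) -> float:
    """Ability at which an n-voter majority first matches the sequential bound.

    Root of ``majority_accuracy(p, n) - pi_max(p)`` in (0.5, 1), found by
    bisection.  For n = 5 the root is ``(3 + sqrt(3)) / 6``, approximately
    0.789: above it five simultaneous voters suffice, below it seven are
    needed.  For n = 3 the difference has no interior root and an error is
    raised.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"n must be a positive odd integer, got {n}")

    def f(p: float) -> float:
        return majority_accuracy(p, n) - pi_max(p)

    lo = 0.5 + bracket_margin
    hi = 1.0 - bracket_margin
    if f(lo) * f(hi) >= 0:
        raise ValueError(
            f"majority_accuracy(p, {n}) - pi_max(p) has no sign change on "
            f"({lo}, {hi}); no interior crossing"
        )
    return float(bisect(f, lo, hi, xtol=xtol))
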