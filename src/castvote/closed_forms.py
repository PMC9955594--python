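"""Closed-form mean performances of sequential chains.

Analytic results for the three scenario families:

* **Equal abilities** — every respondent has ability p.  The casting-vote
  difference d performs a random walk absorbed at +/-2, giving the mean
  performance of the n-th respondent

  ``E[pi_n] = [p^2 + p(1-p)(1-2p) x] / [p^2 + (1-p)^2]``,
  ``x = (2p(1-p))^(k-1)``, ``k = (n+1)/2`` (odd n) or ``n/2`` (even n).

  It equals p at n = 1, 2, rises at every odd step, and converges to
  ``pi_max(p) = p^2 / (p^2 + (1-p)^2)``.

* **One expert** — one respondent has ability q > p among equals.  An
  expert who knows q answers their primary choice whenever
  ``q >= pi_max(p)`` (performance q at any order); otherwise, and always
  when unaware of their edge, their performance follows the damped form
  ``pi_max - (pi_max - q)(2p(1-p))^(k-1)``, increasing in the order n when
  q < pi_max and decreasing when q > pi_max.

* **Three respondents, arbitrary abilities** — a complete case analysis of
  who follows whom, including the drop in the third respondent's mean
  performance when the first respondent is abler than the second (the
  second then reveals nothing, and the simple-majority outcome M becomes
  unreachable).

All formulas here are cross-checked against brute-force enumeration in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .chain import log_odds

logger = logging.getLogger("castvote")

_THREE_PERSON_LABELS = (
    "third_independent",
    "follow_second",
    "simple_majority",
    "follow_first_cascade",
    "third_overrides_cascade",
)


def pi_max(p: float) -> float:
    """Limiting mean performance ``p^2 / (p^2 + (1-p)^2)`` of an equal-ability chain.

    The supremum (over decision order) of mean performance when every
    respondent has ability p; also the posterior accuracy after two
    agreeing independent opinions of ability p.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie in (0, 1), got {p!r}")
    return p * p / (p * p + (1.0 - p) * (1.0 - p))


def half_index(n: int) -> int:
    """Parity index k: ``(n+1)/2`` for odd n, ``n/2`` for even n.

    Counts the completed odd steps of the absorbing d-walk, which is why
    mean performance plateaus across each (odd, even) pair of orders.
    """
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    return (n + 1) // 2 if n % 2 else n // 2


def mean_performance_equal(p: float, n: int) -> float:
    """Mean performance of the n-th respondent in an equal-ability chain.

    Equals p at n = 1 and n = 2, is non-decreasing (strictly increasing
    over odd n), and converges to :func:`pi_max` as n grows: the damping
    factor ``2p(1-p) < 1`` and the sign of ``p(1-p)(1-2p) < 0`` guarantee
    both.
    """
    if not 0.5 < p < 1.0:
        raise ValueError(f"ability must lie in (0.5, 1); got {p!r}")
    k = half_index(n)
    x = (2.0 * p * (1.0 - p)) ** (k - 1)
    q = 1.0 - p
    return (p * p + p * q * (1.0 - 2.0 * p) * x) / (p * p + q * q)


@dataclass(frozen=True)
class ExpertScenario:
    """One high-ability respondent (the expert) among equals.

    Parameters
    ----------
    p:
        Common ability of the non-experts, in (0.5, 1).
    q:
        Expert's true ability, q > p.
    n:
        Expert's decision order (1-based).
    aware:
        Whether the expert knows their true ability q; if not, they (and
        everyone else) treat the expert as an ordinary member of ability p.
    """

    p: float
    q: float
    n: int
    aware: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.p < 1.0:
            raise ValueError(f"p must lie in (0.5, 1); got {self.p!r}")
        if not self.p < self.q < 1.0:
            raise ValueError(
                f"expert ability q must satisfy p < q < 1; got q = {self.q!r}"
            )
        if self.n < 1:
            raise ValueError(f"order must be >= 1, got {self.n}")


def _damped_performance(p: float, q: float, n: int) -> float:
    bound = pi_max(p)
    return bound - (bound - q) * (2.0 * p * (1.0 - p)) ** (half_index(n) - 1)


def expert_performance(scenario: ExpertScenario) -> float:
    """Mean performance of the expert at their decision order.

    An aware expert with ``q >= pi_max(p)`` always answers their primary
    choice, so their performance is q at every order.  Otherwise (aware
    with a modest edge, or unaware of any edge) the expert behaves like an
    ordinary member — primary choice while the casting-vote difference is
    within +/-1, follow the majority once it is absorbed — and performs at
    the damped level ``pi_max - (pi_max - q)(2p(1-p))^(k-1)``.
    """
    if scenario.aware and scenario.q >= pi_max(scenario.p):
        return scenario.q
    return _damped_performance(scenario.p, scenario.q, scenario.n)


@dataclass(frozen=True)
class ThreePersonCase:
    """Outcome of the three-respondent case analysis."""

    label: str
    mean_performances: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.label not in _THREE_PERSON_LABELS:
            raise ValueError(f"unknown case label {self.label!r}")


def simple_majority_accuracy_three(p1: float, p2: float, p3: float) -> float:
    """Accuracy M of an unweighted simultaneous majority of three voters."""
    return (
        p1 * p2 * p3
        + (1.0 - p1) * p2 * p3
        + p1 * (1.0 - p2) * p3
        + p1 * p2 * (1.0 - p3)
    )


def three_person_analysis(
    p1: float, p2: float, p3: float, tol: float = 1e-9
) -> ThreePersonCase:
    """Complete case analysis of the three-respondent chain.

    When the second respondent is abler than the first (p2 > p1) both early
    respondents are casting voters and the third faces three independent
    opinions: they answer independently if their own log-odds weight
    dominates (``third_independent``, mean p3), follow the second if that
    weight dominates (``follow_second``, mean p2), and otherwise take the
    simple majority (``simple_majority``, mean M).

    When the first is abler (p1 > p2) the second follows the first and
    reveals nothing; the third sees a single informative answer and either
    joins the cascade (``follow_first_cascade``, mean p1, when p1 > p3) or
    overrides it with their own primary choice
    (``third_overrides_cascade``, mean p3).  M is unreachable on this side,
    which is why the third's mean performance drops across the p1 = p2
    diagonal in the interior region.

    Ability ties within ``tol`` are resolved by the universal tie rule
    (adopt the primary choice, i.e. like the p2 > p1 branch) with a warning.
    """
    for p in (p1, p2, p3):
        if not 0.5 < p < 1.0:
            raise ValueError(f"abilities must lie in (0.5, 1); got {p!r}")
    r1, r2, r3 = log_odds(p1), log_odds(p2), log_odds(p3)
    if abs(r1 - r2) <= tol:
        logger.warning(
            "p1 and p2 tie within tolerance; the second respondent adopts "
            "their primary choice (casting), as in the p2 > p1 branch"
        )
    if r2 >= r1 - tol:
        # First and second are both casting voters; three independent votes.
        e2 = p2
        if r3 > r1 + r2 + tol:
            return ThreePersonCase("third_independent", (p1, e2, p3))
        if r2 > r1 + r3 + tol:
            return ThreePersonCase("follow_second", (p1, e2, p2))
        return ThreePersonCase(
            "simple_majority", (p1, e2, simple_majority_accuracy_three(p1, p2, p3))
        )
    # p1 > p2: the second follows the first; only the first answer informs.
    e2 = p1
    if abs(r1 - r3) <= tol:
        logger.warning(
            "p1 and p3 tie within tolerance; the third respondent adopts "
            "their primary choice (casting)"
        )
    if r1 > r3 + tol:
        return ThreePersonCase("follow_first_cascade", (p1, e2, p1))
    return ThreePersonCase("third_overrides_cascade", (p1, e2, p3))
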