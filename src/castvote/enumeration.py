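"""Exact brute-force performance computation (ground-truth oracle).

Every quantity here is computed by enumerating the primary-choice
randomness rather than by closed form, so these routines serve as the
independent check for the analytic results and the simulator.  Enumeration
works in the *absolute truth frame*: the correct option is fixed and the
first respondent's primary choice (correct with probability p_1) defines
the ``s`` label, which sidesteps the relative-frame bookkeeping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .chain import (
    DEFAULT_TOL,
    AbilityProfile,
    Label,
    LABELS,
    run_sequence,
)

#: Hard cap on 2^N full enumeration.
MAX_FULL_ENUMERATION = 20


@dataclass(frozen=True)
class PerformanceCurve:
    """Mean performance indexed by decision order (1-based)."""

    orders: tuple[int, ...]
    values: tuple[float, ...]
    standard_errors: Optional[tuple[float, ...]] = None
    kind: str = "exact"

    def __post_init__(self) -> None:
        if len(self.orders) != len(self.values):
            raise ValueError("orders and values must align")
        if self.standard_errors is not None and len(self.standard_errors) != len(
            self.values
        ):
            raise ValueError("standard_errors must align with values")

    def value_at(self, n: int) -> float:
        return self.values[self.orders.index(n)]

    def to_frame(self):
        import pandas as pd

        data = {"order": self.orders, "mean_performance": self.values}
        if self.standard_errors is not None:
            data["se"] = self.standard_errors
        return pd.DataFrame(data)


def primaries_from_correctness(correct: Sequence[bool]) -> list[Label]:
    """Map a correctness vector to primary-choice labels in the s/t frame.

    ``s`` is whatever option the first respondent picked, so respondent i's
    primary is ``s`` exactly when their correctness matches the first's.
    """
    if len(correct) < 1:
        raise ValueError("need at least one respondent")
    first = bool(correct[0])
    return ["s"] + ["s" if bool(c) == first else "t" for c in correct[1:]]


def exact_mean_performance(
    profile: AbilityProfile, n: int, tol: float = DEFAULT_TOL
) -> float:
    """Mean performance of the n-th respondent by full 2^n enumeration.

    Enumerates every correctness vector of the first ``n`` primary choices,
    runs the chain, and accumulates the probability that respondent n's
    answer names the correct option.  Exact identities: the first
    respondent's mean performance is p_1 and the second's is max(p_1, p_2).
    """
    profile._check_index(n)
    if n > MAX_FULL_ENUMERATION:
        raise ValueError(
            f"full enumeration capped at n = {MAX_FULL_ENUMERATION}; "
            "use exact_curve (casting-branch pruning) for longer chains"
        )
    sub = profile.prefix(n)
    p = sub.abilities
    total = 0.0
    for bits in itertools.product((True, False), repeat=n):
        prob = 1.0
        for p_i, c in zip(p, bits):
            prob *= p_i if c else 1.0 - p_i
        result = run_sequence(sub, primaries_from_correctness(bits), tol)
        correct_label = "s" if bits[0] else "t"
        if result.records[n - 1].answer == correct_label:
            total += prob
    return total


def exact_curve(
    profile: AbilityProfile,
    believed: Optional[AbilityProfile] = None,
    tol: float = DEFAULT_TOL,
) -> PerformanceCurve:
    """Exact mean performance of every order, with casting-branch pruning.

    The chain's evolution branches only at casting voters (non-casting
    answers are deterministic given the running partition), so the state
    space is the set of reachable log-odds margins toward the correct
    option, not the 2^N correctness vectors.

    Parameters
    ----------
    believed:
        Abilities every agent *uses in their decision rules* (casting tests
        and evidence weights), when these differ from the true abilities
        that govern primary-choice correctness.  Defaults to ``profile``.
        This models, e.g., an unaware expert treated — by themselves and by
        everyone else — as an ordinary member.
    """
    if believed is None:
        believed = profile
    if len(believed) != len(profile):
        raise ValueError("believed profile must match the true profile in length")
    p = profile.abilities
    r = believed.log_odds_ratios
    # margin (believed log-odds, toward the correct option) -> probability
    states: dict[float, float] = {0.0: 1.0}
    values = []
    for n in range(1, len(profile) + 1):
        r_n = r[n - 1]
        p_n = p[n - 1]
        new_states: dict[float, float] = {}

        def _add(margin: float, prob: float) -> None:
            key = round(margin, 12)
            new_states[key] = new_states.get(key, 0.0) + prob

        correct = 0.0
        for margin, prob in states.items():
            gap = abs(margin)
            casting = gap < r_n - tol or abs(gap - r_n) <= tol
            if casting:
                correct += prob * p_n
                _add(margin + r_n, prob * p_n)
                _add(margin - r_n, prob * (1.0 - p_n))
            else:
                if margin > 0:
                    correct += prob
                _add(margin, prob)
        values.append(correct)
        states = new_states
    return PerformanceCurve(
        orders=tuple(range(1, len(profile) + 1)),
        values=tuple(values),
        kind="exact",
    )


def bayes_optimal_answer(
    profile: AbilityProfile,
    observed_answers: Sequence[Label],
    primary: Label,
    tol: float = DEFAULT_TOL,
) -> Label:
    """Optimal answer by brute-force posterior computation.

    Independent oracle for the casting-vote shortcut: for each hypothesis
    about which option is correct, sum the probability of every antecedent
    primary-choice vector whose induced answer sequence matches the one
    observed, multiply by the focal respondent's own primary-choice factor,
    and answer with the more probable option (primary choice on a tie).
    No casting-voter bookkeeping is used in the inference step.
    """
    n = len(observed_answers) + 1
    profile._check_index(n)
    if primary not in LABELS:
        raise ValueError(f"primary must be 's' or 't', got {primary!r}")
    sub = profile.prefix(n - 1)
    like = {"s": 0.0, "t": 0.0}
    for rest in itertools.product(LABELS, repeat=n - 2):
        primaries = ("s",) + rest
        result = run_sequence(sub, primaries, tol)
        if result.answers != tuple(observed_answers):
            continue
        for hyp in LABELS:
            prob = 1.0
            for i, x in enumerate(primaries, start=1):
                p_i = profile.ability(i)
                prob *= p_i if x == hyp else 1.0 - p_i
            like[hyp] += prob
    p_n = profile.ability(n)
    like["s"] *= p_n if primary == "s" else 1.0 - p_n
    like["t"] *= p_n if primary == "t" else 1.0 - p_n
    if like["s"] <= 0.0 and like["t"] <= 0.0:
        raise ValueError("observed answers are unreachable under the model")
    if abs(math.log(like["s"]) - math.log(like["t"])) <= tol:
        return primary
    return "s" if like["s"] > like["t"] else "t"
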