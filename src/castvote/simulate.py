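"""Seeded Monte-Carlo simulation of sequential decision chains.

Each replicate draws every respondent's primary-choice correctness
independently from their ability, runs the optimal-answer recursion, and
records who answered correctly, who was a casting voter, the casting-vote
difference walk and whether the run was a full cascade (every answer equal
to the first).  One master seed spawns an independent substream per run,
so per-order estimates are reproducible regardless of execution order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .chain import DEFAULT_TOL, AbilityProfile, SequenceResult, run_sequence
from .enumeration import primaries_from_correctness


@dataclass(frozen=True)
class SimulationReport:
    """Aggregated Monte-Carlo estimates for one ability profile.

    ``accuracy[i]`` estimates the mean performance of order ``orders[i]``;
    ``standard_error`` is the binomial SE ``sqrt(est (1 - est) / n_runs)``.
    ``max_abs_d`` is the largest casting-vote difference ``||S| - |T||``
    any respondent observed in any run, and ``cascade_rate`` the fraction
    of runs in which every answer equalled the first.
    """

    orders: tuple[int, ...]
    abilities: tuple[float, ...]
    accuracy: tuple[float, ...]
    standard_error: tuple[float, ...]
    casting_fraction: tuple[float, ...]
    max_abs_d: int
    cascade_rate: float
    n_runs: int
    seed: int

    @property
    def per_order_accuracy(self) -> list[tuple[int, float, float]]:
        return list(zip(self.orders, self.accuracy, self.standard_error))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "order": self.orders,
                "ability": self.abilities,
                "accuracy": self.accuracy,
                "se": self.standard_error,
                "casting_fraction": self.casting_fraction,
            }
        )


@dataclass(frozen=True)
class DWalkStatistics:
    """Absorption statistics of the equal-ability casting-vote walk."""

    max_abs_d: int
    #: order at which |d| first reached 2 -> number of runs; runs in which
    #: the walk was never absorbed are counted under ``unabsorbed_runs``.
    absorption_orders: dict[int, int]
    unabsorbed_runs: int
    n_runs: int
    seed: int


def _iter_runs(
    profile: AbilityProfile, n_runs: int, seed: int, tol: float
) -> Iterator[SequenceResult]:
    """Yield one chain realisation per spawned RNG substream."""
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    abilities = np.asarray(profile.abilities)
    for child in np.random.SeedSequence(seed).spawn(n_runs):
        rng = np.random.default_rng(child)
        correct = rng.random(len(profile)) < abilities
        yield run_sequence(
            profile,
            primaries_from_correctness(correct),
            tol,
            truth="s" if correct[0] else "t",
        )


def _d_trace(result: SequenceResult) -> list[int]:
    """Casting-vote difference d_n each respondent observed (n = 1..N)."""
    trace = []
    d = 0
    for rec in result.records:
        trace.append(d)
        if rec.is_casting:
            d += 1 if rec.answer == "s" else -1
    return trace


def simulate(
    profile: AbilityProfile,
    n_runs: int = 10_000,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> SimulationReport:
    """Monte-Carlo per-order accuracy estimates for a profile.

    Deterministic given ``(profile, n_runs, seed)``.
    """
    n = len(profile)
    correct_counts = np.zeros(n, dtype=np.int64)
    casting_counts = np.zeros(n, dtype=np.int64)
    cascade_count = 0
    max_abs_d = 0
    for result in _iter_runs(profile, n_runs, seed, tol):
        for i, rec in enumerate(result.records):
            if rec.answer == result.truth:
                correct_counts[i] += 1
            if rec.is_casting:
                casting_counts[i] += 1
        if all(ans == "s" for ans in result.answers):
            cascade_count += 1
        run_max = max(abs(d) for d in _d_trace(result))
        max_abs_d = max(max_abs_d, run_max)
    accuracy = correct_counts / n_runs
    se = np.sqrt(accuracy * (1.0 - accuracy) / n_runs)
    return SimulationReport(
        orders=tuple(range(1, n + 1)),
        abilities=profile.abilities,
        accuracy=tuple(accuracy.tolist()),
        standard_error=tuple(se.tolist()),
        casting_fraction=tuple((casting_counts / n_runs).tolist()),
        max_abs_d=int(max_abs_d),
        cascade_rate=cascade_count / n_runs,
        n_runs=n_runs,
        seed=seed,
    )


def d_walk_statistics(
    profile: AbilityProfile,
    n_runs: int = 10_000,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> DWalkStatistics:
    """Absorption statistics of the casting-vote difference walk.

    Requires an equal-ability profile, for which d_n moves by +/-1 at each
    casting voter and freezes once it reaches +/-2 (every later respondent
    is non-casting).  Both properties are hard-asserted per run, not
    estimated.  Uses the same substream discipline as :func:`simulate`, so
    identical seeds reproduce identical trajectories.
    """
    if not profile.is_equal_ability:
        raise ValueError("the d-walk is defined for equal-ability profiles only")
    max_abs_d = 0
    absorption: Counter[int] = Counter()
    unabsorbed = 0
    for result in _iter_runs(profile, n_runs, seed, tol):
        trace = _d_trace(result)
        first_hit: Optional[int] = None
        for order, d in enumerate(trace, start=1):
            if abs(d) > 2:
                raise AssertionError(f"|d| exceeded 2 at order {order}: {trace}")
            if first_hit is None and abs(d) == 2:
                first_hit = order
            elif first_hit is not None and d != trace[first_hit - 1]:
                raise AssertionError(
                    f"d changed after absorption at order {first_hit}: {trace}"
                )
        max_abs_d = max(max_abs_d, max(abs(d) for d in trace))
        if first_hit is None:
            unabsorbed += 1
        else:
            absorption[first_hit] += 1
    return DWalkStatistics(
        max_abs_d=int(max_abs_d),
        absorption_orders=dict(sorted(absorption.items())),
        unabsorbed_runs=unabsorbed,
        n_runs=n_runs,
        seed=seed,
    )
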