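"""Sequential binary decision chains and the casting-vote recursion.

A group of N respondents answers a binary question (one correct option) in
a fixed order.  Respondent n holds a private *primary choice*, correct with
probability p_n (their *ability*, strictly between 0.5 and 1), observes all
earlier public *answers*, and answers so as to maximise the probability of
being correct given what they know.  Options are labelled relative to the
first answer: ``s`` is the option the first respondent chose, ``t`` the
other one.

Rational answering reduces to a weighted vote among *casting voters* — the
antecedents whose answer reveals their primary choice.  Respondent n
compares the gap between the summed log-odds weights of casting voters on
each side with their own log-odds weight ``r*_n = log(p_n / (1 - p_n))``:

* if the gap is smaller, their own primary choice tips the scales — they
  are a casting voter and answer their primary choice;
* otherwise they side with the heavier set, and their answer carries no
  information about their primary choice (non-casting).

Non-casting voters contribute nothing to anyone's likelihood, which is what
makes the recursion tractable: the state carried along the chain is just
the partition of earlier respondents into casting-``s`` / casting-``t`` /
non-casting index sets.  Ties (the log-odds gap equal to ``r*_n`` within a
tolerance) resolve to the primary choice and count as casting, which for
equal abilities reproduces the vote-difference random walk absorbed at
``|d| = 2``.

Respondents are indexed 1-based throughout the public surface.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

logger = logging.getLogger("castvote")

#: Default tolerance for log-odds comparisons (log domain).
DEFAULT_TOL = 1e-9

Label = Literal["s", "t"]

#: The two choice labels, in the frame anchored at the first answer.
LABELS: tuple[Label, Label] = ("s", "t")


def other_label(label: Label) -> Label:
    """The opposite choice label (``s`` <-> ``t``)."""
    if label not in LABELS:
        raise ValueError(f"label must be 's' or 't', got {label!r}")
    return "t" if label == "s" else "s"


def log_odds(p: float) -> float:
    """Log-odds ratio ``log(p / (1 - p))`` of a success probability.

    Strictly increasing in ``p``; zero at 0.5 and positive above it.  This
    is both the optimal vote weight in simultaneous weighted majority
    voting and the additive evidence unit of the sequential recursion.

    Parameters
    ----------
    p:
        Probability in the open interval (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p!r}")
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class AbilityProfile:
    """Ordered per-respondent success probabilities.

    Parameters
    ----------
    abilities:
        One probability per respondent, each strictly in (0.5, 1); index n
        (1-based) is the n-th respondent in decision order.
    strict_distinct:
        Assert that abilities are pairwise distinct.  The generic theory
        assumes subset odds products never tie; validating all ``2^N``
        subset products is exponential, so only pairwise distinctness is
        checked and the universal tie rule covers the rest.
    """

    abilities: tuple[float, ...]
    strict_distinct: bool = False

    def __post_init__(self) -> None:
        abilities = tuple(float(p) for p in self.abilities)
        object.__setattr__(self, "abilities", abilities)
        if len(abilities) < 1:
            raise ValueError("an ability profile needs at least one respondent")
        for p in abilities:
            if not 0.5 < p < 1.0:
                raise ValueError(
                    f"abilities must lie strictly in (0.5, 1); got {p!r}"
                    " (0.5 is a coin flip, 1 is infallibility; both excluded)"
                )
        if self.strict_distinct and len(set(abilities)) != len(abilities):
            raise ValueError("strict_distinct profile has tied abilities")
        object.__setattr__(
            self, "_log_odds", tuple(log_odds(p) for p in abilities)
        )

    def __len__(self) -> int:
        return len(self.abilities)

    @property
    def n(self) -> int:
        """Number of respondents."""
        return len(self.abilities)

    @property
    def log_odds_ratios(self) -> tuple[float, ...]:
        """Log-odds weight ``r*_n`` of every respondent, in order."""
        return self._log_odds  # type: ignore[attr-defined]

    @property
    def is_equal_ability(self) -> bool:
        return len(set(self.abilities)) == 1

    def _check_index(self, n: int) -> None:
        if not 1 <= n <= len(self.abilities):
            raise IndexError(f"respondent index {n} outside 1..{len(self.abilities)}")

    def ability(self, n: int) -> float:
        """Ability of the n-th respondent (1-based)."""
        self._check_index(n)
        return self.abilities[n - 1]

    def log_odds_of(self, n: int) -> float:
        """Log-odds weight ``r*_n`` of the n-th respondent (1-based)."""
        self._check_index(n)
        return self._log_odds[n - 1]  # type: ignore[attr-defined]

    def prefix(self, n: int) -> "AbilityProfile":
        """Sub-profile of the first ``n`` respondents."""
        self._check_index(n)
        return AbilityProfile(self.abilities[:n], self.strict_distinct)


@dataclass(frozen=True)
class VotePartition:
    """Disjoint index sets of casting-``s``, casting-``t`` and non-casting voters.

    ``S`` and ``T`` hold casting voters whose answer (equal to their primary
    choice) was ``s`` and ``t`` respectively; ``R`` holds non-casting
    voters.  The three sets partition ``{1..n_seen}`` and, by the framing
    convention, respondent 1 always sits in ``S``.

    ``anchor_first=False`` relaxes only the "1 in S" convention so that
    mirrored (``s``/``t``-swapped) partitions can be formed; it is excluded
    from equality comparisons.
    """

    S: frozenset[int]
    T: frozenset[int]
    R: frozenset[int]
    n_seen: int
    anchor_first: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", frozenset(self.S))
        object.__setattr__(self, "T", frozenset(self.T))
        object.__setattr__(self, "R", frozenset(self.R))
        if self.n_seen < 0:
            raise ValueError("n_seen must be non-negative")
        total = len(self.S) + len(self.T) + len(self.R)
        union = self.S | self.T | self.R
        if total != len(union) or union != set(range(1, self.n_seen + 1)):
            raise ValueError(
                "S, T, R must disjointly cover indices 1..n_seen; got "
                f"S={sorted(self.S)}, T={sorted(self.T)}, R={sorted(self.R)}, "
                f"n_seen={self.n_seen}"
            )
        if self.anchor_first and self.n_seen >= 1 and 1 not in self.S:
            raise ValueError("respondent 1 defines the 's' frame and belongs to S")

    @classmethod
    def initial(cls) -> "VotePartition":
        """Partition after the first respondent answered: ``S={1}``."""
        return cls(frozenset({1}), frozenset(), frozenset(), 1)

    @property
    def d(self) -> int:
        """Casting-vote difference ``|S| - |T|`` (signed)."""
        return len(self.S) - len(self.T)

    def margin(self, profile: AbilityProfile) -> float:
        """Log-odds evidence margin ``sum_{m in S} r*_m - sum_{m in T} r*_m``."""
        r = profile.log_odds_ratios
        return sum(r[m - 1] for m in self.S) - sum(r[m - 1] for m in self.T)

    def extended(self, n: int, group: str) -> "VotePartition":
        """New partition with respondent ``n = n_seen + 1`` added to ``group``.

        ``group`` is ``"S"``, ``"T"`` or ``"R"``.
        """
        if n != self.n_seen + 1:
            raise ValueError(f"expected next index {self.n_seen + 1}, got {n}")
        if group == "S":
            return VotePartition(self.S | {n}, self.T, self.R, n, self.anchor_first)
        if group == "T":
            return VotePartition(self.S, self.T | {n}, self.R, n, self.anchor_first)
        if group == "R":
            return VotePartition(self.S, self.T, self.R | {n}, n, self.anchor_first)
        raise ValueError(f"group must be 'S', 'T' or 'R', got {group!r}")


def _check_partition(partition: VotePartition, profile: AbilityProfile) -> None:
    if partition.n_seen > len(profile):
        raise IndexError(
            f"partition covers {partition.n_seen} respondents but the profile "
            f"has only {len(profile)}"
        )


def log_pair_likelihoods(
    partition: VotePartition, profile: AbilityProfile
) -> tuple[float, float]:
    """Log-likelihoods ``(log L_s, log L_t)`` of each option being correct.

    Only casting voters enter; non-casting voters' answers are deterministic
    given their antecedents and carry no evidence.  Empty products are 1
    (log 0.0).  All chain-internal comparisons use this log form so that
    long chains cannot underflow.
    """
    _check_partition(partition, profile)
    p = profile.abilities
    ls = 0.0
    lt = 0.0
    for m in partition.S:
        ls += math.log(p[m - 1])
        lt += math.log(1.0 - p[m - 1])
    for m in partition.T:
        ls += math.log(1.0 - p[m - 1])
        lt += math.log(p[m - 1])
    return ls, lt


def pair_likelihoods(
    partition: VotePartition, profile: AbilityProfile
) -> tuple[float, float]:
    """Likelihoods ``(L_s, L_t)`` of each option being correct.

    ``L_s = prod_{m in S} p_m * prod_{m in T} (1 - p_m)`` and symmetrically
    for ``L_t``; determined solely by the casting voters' abilities.
    """
    ls, lt = log_pair_likelihoods(partition, profile)
    return math.exp(ls), math.exp(lt)


def optimal_answer(
    primary: Label,
    partition: VotePartition,
    profile: AbilityProfile,
    n: int,
    tol: float = DEFAULT_TOL,
) -> tuple[Label, bool]:
    """Optimal answer of the n-th respondent and their casting status.

    Let ``delta`` be the casting-vote log-odds margin in favour of ``s``.
    If ``|delta| < r*_n`` the respondent's own primary choice decides: they
    are a casting voter and answer it.  Otherwise they follow the heavier
    side, ignoring their primary choice.  When ``|delta|`` and ``r*_n``
    agree within ``tol`` either option is equally likely to be correct and
    the respondent adopts their primary choice (counted as casting).

    Returns
    -------
    (answer, is_casting)
    """
    if n < 2:
        raise ValueError("the first respondent answers their primary choice; n >= 2")
    if partition.n_seen != n - 1:
        raise ValueError(
            f"partition covers {partition.n_seen} antecedents; expected {n - 1}"
        )
    _check_partition(partition, profile)
    if primary not in LABELS:
        raise ValueError(f"primary must be 's' or 't', got {primary!r}")
    r_n = profile.log_odds_of(n)
    delta = partition.margin(profile)
    if abs(abs(delta) - r_n) <= tol:
        level = logging.WARNING if profile.strict_distinct else logging.DEBUG
        logger.log(
            level,
            "tie at respondent %d: |margin| = %.12g within tol of r*_n = %.12g; "
            "adopting the primary choice",
            n,
            abs(delta),
            r_n,
        )
        return primary, True
    if abs(delta) < r_n:
        return primary, True
    return ("s" if delta > 0 else "t"), False


def conditional_performance(
    partition: VotePartition,
    primary: Label,
    profile: AbilityProfile,
    n: int,
    tol: float = DEFAULT_TOL,
) -> float:
    """Maximised probability that the n-th respondent answers correctly.

    Conditional on the observed casting-vote partition and the respondent's
    own primary choice: the larger of the two hypothesis joint
    probabilities (casting-voter likelihood times the respondent's own
    primary-choice factor) divided by their sum.  Always in [0.5, 1];
    computed in log space.
    """
    if partition.n_seen != n - 1:
        raise ValueError(
            f"partition covers {partition.n_seen} antecedents; expected {n - 1}"
        )
    _check_partition(partition, profile)
    if primary not in LABELS:
        raise ValueError(f"primary must be 's' or 't', got {primary!r}")
    p_n = profile.ability(n)
    ls, lt = log_pair_likelihoods(partition, profile)
    if primary == "s":
        a = ls + math.log(p_n)
        b = lt + math.log(1.0 - p_n)
    else:
        a = ls + math.log(1.0 - p_n)
        b = lt + math.log(p_n)
    hi, lo = (a, b) if a >= b else (b, a)
    return 1.0 / (1.0 + math.exp(lo - hi))


@dataclass(frozen=True)
class DecisionRecord:
    """One respondent's realised decision within a chain."""

    index: int
    primary: Label
    answer: Label
    is_casting: bool
    conditional_performance: float

    def __post_init__(self) -> None:
        if self.is_casting and self.answer != self.primary:
            raise ValueError("a casting voter's answer equals their primary choice")
        if not 0.5 - 1e-12 <= self.conditional_performance <= 1.0 + 1e-12:
            raise ValueError(
                f"conditional performance {self.conditional_performance!r} "
                "outside [0.5, 1]"
            )


@dataclass(frozen=True)
class SequenceResult:
    """Full record of one realised decision chain."""

    profile: AbilityProfile
    records: tuple[DecisionRecord, ...]
    final_partition: VotePartition
    #: Which label is the correct option, when the harness knows it
    #: (never visible to the agents, whose frame is purely s/t).
    truth: Optional[Label] = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.profile):
            raise ValueError("one record per respondent required")
        if self.final_partition.n_seen != len(self.profile):
            raise ValueError("final partition must cover all respondents")

    @property
    def answers(self) -> tuple[Label, ...]:
        return tuple(rec.answer for rec in self.records)

    @property
    def primaries(self) -> tuple[Label, ...]:
        return tuple(rec.primary for rec in self.records)

    def to_dict(self) -> dict:
        return {
            "abilities": list(self.profile.abilities),
            "truth": self.truth,
            "records": [
                {
                    "index": rec.index,
                    "primary": rec.primary,
                    "answer": rec.answer,
                    "is_casting": rec.is_casting,
                    "conditional_performance": rec.conditional_performance,
                }
                for rec in self.records
            ],
            "final_partition": {
                "S": sorted(self.final_partition.S),
                "T": sorted(self.final_partition.T),
                "R": sorted(self.final_partition.R),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self):
        """Tidy table, one row per respondent."""
        import pandas as pd

        return pd.DataFrame(
            {
                "index": [rec.index for rec in self.records],
                "ability": list(self.profile.abilities),
                "primary": [rec.primary for rec in self.records],
                "answer": [rec.answer for rec in self.records],
                "is_casting": [rec.is_casting for rec in self.records],
                "conditional_performance": [
                    rec.conditional_performance for rec in self.records
                ],
            }
        )


def run_sequence(
    profile: AbilityProfile,
    primaries: Sequence[Label],
    tol: float = DEFAULT_TOL,
    truth: Optional[Label] = None,
) -> SequenceResult:
    """Run one decision chain under the optimal-answer recursion.

    Starting from ``S = {1}, T = R = {}``, each later respondent applies
    :func:`optimal_answer`; casting voters join ``S`` or ``T`` according to
    their primary choice, non-casting voters join ``R``.  A non-casting
    voter's answer never depends on their own primary choice.

    Parameters
    ----------
    primaries:
        One label per respondent, in the frame of the first answer (the
        first entry is ``s`` by definition).
    truth:
        Optionally, which label is the correct option (harness bookkeeping
        only; does not influence any decision).
    """
    if len(primaries) != len(profile):
        raise ValueError(
            f"{len(primaries)} primary choices for {len(profile)} respondents"
        )
    if primaries[0] != "s":
        raise ValueError("the first respondent's primary choice defines 's'")
    for x in primaries:
        if x not in LABELS:
            raise ValueError(f"primary choices must be 's' or 't', got {x!r}")
    records = [
        DecisionRecord(
            index=1,
            primary="s",
            answer="s",
            is_casting=True,
            conditional_performance=profile.ability(1),
        )
    ]
    partition = VotePartition.initial()
    for n in range(2, len(profile) + 1):
        primary = primaries[n - 1]
        answer, is_casting = optimal_answer(primary, partition, profile, n, tol)
        pi_n = conditional_performance(partition, primary, profile, n, tol)
        records.append(
            DecisionRecord(
                index=n,
                primary=primary,
                answer=answer,
                is_casting=is_casting,
                conditional_performance=pi_n,
            )
        )
        group = ("S" if primary == "s" else "T") if is_casting else "R"
        partition = partition.extended(n, group)
    return SequenceResult(
        profile=profile,
        records=tuple(records),
        final_partition=partition,
        truth=truth,
    )
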