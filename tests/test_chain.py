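"""Unit and property tests for the decision-chain core."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castvote import (
    AbilityProfile,
    VotePartition,
    conditional_performance,
    generate_profile,
    log_odds,
    optimal_answer,
    pair_likelihoods,
    run_sequence,
)

abilities_st = st.floats(0.51, 0.99)


class TestLogOdds:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 0.0), (0.8, 1.3863), (0.7, 0.8473)],
    )
    def test_reference_values(self, p, expected):
        assert log_odds(p) == pytest.approx(expected, abs=5e-5)

    def test_monotone_and_signed(self):
        grid = [0.05, 0.3, 0.5, 0.51, 0.7, 0.95]
        values = [log_odds(p) for p in grid]
        assert values == sorted(values)
        assert all(v > 0 for p, v in zip(grid, values) if p > 0.5)
        assert all(v < 0 for p, v in zip(grid, values) if p < 0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            log_odds(p)


class TestAbilityProfile:
    def test_rejects_out_of_range_abilities(self):
        for bad in [(0.5,), (1.0,), (0.4, 0.7), ()]:
            with pytest.raises(ValueError):
                AbilityProfile(bad)

    def test_strict_distinct_rejects_ties(self):
        with pytest.raises(ValueError):
            AbilityProfile((0.7, 0.7), strict_distinct=True)

    def test_log_odds_monotone_in_ability(self):
        profile = AbilityProfile((0.6, 0.9, 0.7))
        r = profile.log_odds_ratios
        assert r[1] > r[2] > r[0] > 0


class TestVotePartition:
    def test_first_respondent_anchors_s(self):
        with pytest.raises(ValueError):
            VotePartition(frozenset(), frozenset({1}), frozenset(), 1)

    def test_sets_must_cover_disjointly(self):
        with pytest.raises(ValueError):
            VotePartition(frozenset({1}), frozenset({1}), frozenset(), 2)
        with pytest.raises(ValueError):
            VotePartition(frozenset({1}), frozenset(), frozenset(), 2)

    def test_d_is_signed_count_difference(self):
        part = VotePartition(frozenset({1, 3}), frozenset({2}), frozenset({4}), 4)
        assert part.d == 1


class TestPairLikelihoods:
    def test_two_casting_voters(self):
        part = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        ls, lt = pair_likelihoods(part, AbilityProfile((0.6, 0.8)))
        assert (ls, lt) == (pytest.approx(0.12), pytest.approx(0.32))

    def test_single_voter(self):
        ls, lt = pair_likelihoods(VotePartition.initial(), AbilityProfile((0.9,)))
        assert (ls, lt) == (pytest.approx(0.9), pytest.approx(0.1))

    def test_non_casting_voter_contributes_nothing(self):
        part = VotePartition(frozenset({1}), frozenset({2}), frozenset({3}), 3)
        ls, lt = pair_likelihoods(part, AbilityProfile((0.6, 0.8, 0.99)))
        assert (ls, lt) == (pytest.approx(0.12), pytest.approx(0.32))


class TestOptimalAnswer:
    def test_second_follows_abler_first(self):
        profile = AbilityProfile((0.8, 0.6))
        answer, casting = optimal_answer("t", VotePartition.initial(), profile, 2)
        assert (answer, casting) == ("s", False)

    def test_abler_second_keeps_primary(self):
        profile = AbilityProfile((0.6, 0.8))
        answer, casting = optimal_answer("t", VotePartition.initial(), profile, 2)
        assert (answer, casting) == ("t", True)

    def test_third_overruled_by_stronger_t_side(self):
        profile = AbilityProfile((0.6, 0.8, 0.7))
        part = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        answer, casting = optimal_answer("s", part, profile, 3)
        assert (answer, casting) == ("t", False)

    def test_equal_ability_tie_adopts_primary(self):
        # one casting vote for s, own weight equal: either option equally likely
        profile = AbilityProfile((0.7, 0.7))
        for primary in "st":
            answer, casting = optimal_answer(primary, VotePartition.initial(), profile, 2)
            assert (answer, casting) == (primary, True)

    def test_usage_errors(self):
        profile = AbilityProfile((0.6, 0.8))
        with pytest.raises(ValueError):
            optimal_answer("s", VotePartition.initial(), profile, 1)
        part3 = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        with pytest.raises(ValueError):
            optimal_answer("s", part3, profile, 2)  # partition covers too many


class TestRunSequence:
    def test_equal_ability_hand_trace(self):
        result = run_sequence(AbilityProfile((0.7,) * 5), ["s", "t", "t", "t", "s"])
        assert result.answers == ("s", "t", "t", "t", "t")
        assert sorted(result.final_partition.S | result.final_partition.T) == [1, 2, 3, 4]
        assert sorted(result.final_partition.R) == [5]

    def test_highest_ability_first_cascades(self):
        result = run_sequence(AbilityProfile((0.9, 0.6, 0.7)), ["s", "t", "t"])
        assert result.answers == ("s", "s", "s")
        assert sorted(result.final_partition.R) == [2, 3]

    def test_single_respondent(self):
        result = run_sequence(AbilityProfile((0.8,)), ["s"])
        assert result.answers == ("s",)
        assert result.records[0].is_casting

    def test_first_primary_must_define_frame(self):
        with pytest.raises(ValueError):
            run_sequence(AbilityProfile((0.7, 0.8)), ["t", "s"])

    def test_casting_voters_answer_their_primary(self, random_profile_factory):
        for seed in range(5):
            profile = random_profile_factory(6, seed)
            for rest in itertools.product("st", repeat=5):
                result = run_sequence(profile, ("s",) + rest)
                for rec in result.records:
                    if rec.is_casting:
                        assert rec.answer == rec.primary

    def test_non_casting_answer_independent_of_own_primary(self, random_profile_factory):
        profile = random_profile_factory(6, 11)
        for rest in itertools.product("st", repeat=5):
            result = run_sequence(profile, ("s",) + rest)
            for rec in result.records[1:]:
                if rec.is_casting:
                    continue
                flipped = list(("s",) + rest)
                flipped[rec.index - 1] = "t" if rec.primary == "s" else "s"
                other = run_sequence(profile, flipped)
                assert other.answers[rec.index - 1] == rec.answer

    def test_r_member_ability_never_matters(self, random_profile_factory, rng):
        # perturbing a non-casting voter's ability changes no answer as long
        # as the member stays non-casting
        checked = 0
        for seed in range(20):
            profile = random_profile_factory(6, 100 + seed)
            primaries = ("s",) + tuple(rng.choice(["s", "t"], size=5))
            base = run_sequence(profile, primaries)
            for idx in sorted(base.final_partition.R):
                new = list(profile.abilities)
                new[idx - 1] = min(max(new[idx - 1] + rng.normal(0, 0.02), 0.51), 0.99)
                perturbed = run_sequence(AbilityProfile(tuple(new)), primaries)
                if idx in perturbed.final_partition.R:
                    assert perturbed.answers == base.answers
                    checked += 1
        assert checked > 10


class TestConditionalPerformance:
    def test_split_casting_votes(self):
        part = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        pi = conditional_performance(part, "s", AbilityProfile((0.6, 0.8, 0.7)), 3)
        assert pi == pytest.approx(0.096 / 0.18, abs=1e-12)

    def test_second_respondent_closed_form(self):
        p1, p2 = 0.6, 0.8
        pi = conditional_performance(
            VotePartition.initial(), "s", AbilityProfile((p1, p2)), 2
        )
        assert pi == pytest.approx(p1 * p2 / (p1 * p2 + (1 - p1) * (1 - p2)), abs=1e-14)

    def test_tied_hypotheses_floor_at_half(self):
        # symmetric evidence: one casting vote each way with equal abilities
        part = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        pi = conditional_performance(part, "s", AbilityProfile((0.7, 0.7, 0.7)), 3)
        assert pi == pytest.approx(0.7)
        part0 = VotePartition(frozenset({1}), frozenset({2}), frozenset(), 2)
        # equal abilities, opposite votes, weak self: still >= 0.5
        pi2 = conditional_performance(part0, "s", AbilityProfile((0.7, 0.7, 0.51)), 3)
        assert 0.5 <= pi2 <= 1.0

    @given(
        p=st.tuples(abilities_st, abilities_st, abilities_st),
        primary=st.sampled_from(["s", "t"]),
        membership=st.sampled_from("STR"),
    )
    @settings(max_examples=200, deadline=None)
    def test_frame_symmetry_and_blind_floor(self, p, primary, membership):
        """Swapping the s/t roles mirrors likelihoods and preserves pi_n, and
        optimal conditioning beats blindly answering the primary choice."""
        profile = AbilityProfile(p)
        sets = {"S": {1}, "T": set(), "R": set()}
        sets[membership].add(2)
        part = VotePartition(
            frozenset(sets["S"]), frozenset(sets["T"]), frozenset(sets["R"]), 2
        )
        mirror = VotePartition(
            frozenset(sets["T"]), frozenset(sets["S"]), frozenset(sets["R"]), 2,
            anchor_first=False,
        )
        ls, lt = pair_likelihoods(part, profile)
        ms, mt = pair_likelihoods(mirror, profile)
        assert ls == pytest.approx(mt) and lt == pytest.approx(ms)
        other = "t" if primary == "s" else "s"
        pi = conditional_performance(part, primary, profile, 3)
        assert pi == pytest.approx(conditional_performance(mirror, other, profile, 3))
        # blind accuracy of always answering the primary, same conditioning
        p3 = profile.ability(3)
        a = ls * (p3 if primary == "s" else 1 - p3)
        b = lt * (p3 if primary == "t" else 1 - p3)
        blind = a / (a + b)
        assert pi >= blind - 1e-12
        assert 0.5 - 1e-12 <= pi <= 1.0

    def test_mean_of_conditional_equals_truth_frame_accuracy(
        self, random_profile_factory
    ):
        """Averaging pi_n over the primary-choice distribution reproduces the
        truth-frame probability of a correct answer (frame consistency)."""
        from castvote import exact_mean_performance

        profile = random_profile_factory(5, 7)
        p = profile.abilities
        for n in range(1, 6):
            total = 0.0
            for rest in itertools.product("st", repeat=n - 1):
                primaries = ("s",) + rest
                result = run_sequence(profile.prefix(n), primaries)
                # P(primary vector) summed over both truth hypotheses
                prob = 0.0
                for hyp_weighting in ((p[0], "s"), (1 - p[0], "t")):
                    w, hyp = hyp_weighting
                    for i, x in enumerate(primaries[1:], start=2):
                        w *= p[i - 1] if x == hyp else 1 - p[i - 1]
                    prob += w
                total += prob * result.records[n - 1].conditional_performance
            assert total == pytest.approx(exact_mean_performance(profile, n), abs=1e-12)


class TestSerialisation:
    def test_json_and_frame_round_trip(self):
        import json

        result = run_sequence(AbilityProfile((0.7, 0.8, 0.6)), ["s", "t", "s"])
        payload = json.loads(result.to_json())
        assert [rec["index"] for rec in payload["records"]] == [1, 2, 3]
        assert set(payload["final_partition"]) == {"S", "T", "R"}
        frame = result.to_frame()
        assert list(frame.columns) == [
            "index", "ability", "primary", "answer", "is_casting",
            "conditional_performance",
        ]
        assert frame.shape == (3, 6)
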