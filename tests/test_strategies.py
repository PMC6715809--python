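"""Null strategies: policy rules, simulation traces, generator certification
and compliance scoring."""

import numpy as np
import pytest

from morphmaze import (
    Policy,
    PolicyState,
    SequenceConstraints,
    Side,
    audit_generator,
    compliance,
    enumerate_valid_sequences,
    generate_sequence,
    policy_choice,
    sample_accepted_matrix,
    simulate_strategy,
)
from morphmaze.strategies import ALL_POLICIES, _simulate_policy_matrix
from conftest import sides

L, R = Side.LEFT, Side.RIGHT


class TestPolicyChoice:
    def test_win_stay_returns_last_rewarded(self):
        rng = np.random.default_rng(0)
        state = PolicyState(last_choice=R, last_rewarded_side=L)
        assert policy_choice(Policy.WIN_STAY, state, rng) is L

    def test_win_shift_returns_complement(self):
        rng = np.random.default_rng(0)
        state = PolicyState(last_choice=L, last_rewarded_side=L)
        assert policy_choice(Policy.WIN_SHIFT, state, rng) is R

    def test_spontaneous_alternation_complements_last_choice(self):
        rng = np.random.default_rng(0)
        state = PolicyState(last_choice=R, last_rewarded_side=L)
        assert policy_choice(Policy.SPONT_ALTERNATE, state, rng) is L

    def test_no_reward_yet_fallback_uses_last_choice(self):
        rng = np.random.default_rng(0)
        state = PolicyState(last_choice=L, last_rewarded_side=None)
        assert policy_choice(Policy.WIN_STAY, state, rng) is L
        assert policy_choice(Policy.WIN_SHIFT, state, rng) is R

    def test_constant_policies(self):
        rng = np.random.default_rng(0)
        assert policy_choice(Policy.ALWAYS_LEFT, PolicyState(), rng) is L
        assert policy_choice(Policy.ALWAYS_RIGHT, PolicyState(), rng) is R


class TestSimulateStrategy:
    def test_always_left_on_all_left_schedule(self):
        res = simulate_strategy(Policy.ALWAYS_LEFT, [L, L, L, L])
        assert res.percent_correct == 100.0

    def test_win_shift_hand_trace(self):
        # schedule L R R L, first choice L:
        # t1 L==L reward(L); t2 shift->R==R reward(R); t3 shift->L != R;
        # t4 last reward still R, shift->L == L  => 3/4 correct
        res = simulate_strategy(
            Policy.WIN_SHIFT, sides("LRRL"), first_choice=L
        )
        assert res.per_trial_choices == (L, R, L, L)
        assert res.percent_correct == 75.0

    def test_percent_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            schedule = [Side(int(v)) for v in rng.integers(0, 2, n)]
            policy = ALL_POLICIES[int(rng.integers(0, len(ALL_POLICIES)))]
            seed = int(rng.integers(0, 2**31))
            res = simulate_strategy(policy, schedule, seed=seed)
            n_match = sum(
                c is s for c, s in zip(res.per_trial_choices, schedule)
            )
            assert res.percent_correct == pytest.approx(100 * n_match / n)
            assert len(res.per_trial_choices) == n

    def test_win_stay_win_shift_complementary_on_shared_history(self):
        # driven by the same choice/reward history (the compliance setting),
        # win-stay and win-shift predict complementary sides on every trial,
        # so their compliance scores on any response stream sum to 100%
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            responses = [Side(int(v)) for v in rng.integers(0, 2, n)]
            outcomes = list(rng.integers(0, 2, n).astype(bool))
            state = PolicyState()
            state.update(responses[0], outcomes[0])
            for t in range(1, n):
                stay = policy_choice(Policy.WIN_STAY, state, rng)
                shift = policy_choice(Policy.WIN_SHIFT, state, rng)
                assert shift is stay.complement
                state.update(responses[t], outcomes[t])
            total = compliance(responses, outcomes, Policy.WIN_STAY) + compliance(
                responses, outcomes, Policy.WIN_SHIFT
            )
            assert total == pytest.approx(100.0)

    def test_random_policy_near_chance(self):
        vals = [
            simulate_strategy(
                Policy.RANDOM, generate_sequence(25, seed=s).sides, seed=s
            ).percent_correct
            for s in range(400)
        ]
        assert np.mean(vals) == pytest.approx(50.0, abs=2.5)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_strategy(Policy.RANDOM, [])


class TestVectorisedEquivalence:
    """The matrix simulator used for audits equals the scalar one trace-for-trace."""

    @pytest.mark.parametrize(
        "policy",
        [Policy.ALWAYS_LEFT, Policy.ALWAYS_RIGHT, Policy.WIN_STAY,
         Policy.WIN_SHIFT, Policy.SPONT_ALTERNATE],
    )
    def test_matches_scalar(self, policy):
        rng = np.random.default_rng(3)
        x = sample_accepted_matrix(200, 15, rng=rng)
        firsts = np.random.default_rng(4).integers(0, 2, size=200, dtype=np.int8)
        pct = _simulate_policy_matrix(
            policy, x, np.random.default_rng(0), first_choices=firsts
        )
        for i in range(200):
            res = simulate_strategy(
                policy, [Side(int(v)) for v in x[i]],
                first_choice=Side(int(firsts[i])),
            )
            assert pct[i] == pytest.approx(res.percent_correct)


class TestAuditGenerator:
    def test_trivial_ceiling_always_certifies(self):
        audit = audit_generator(
            session_lengths=[10], n_sequences=50, seed=0, ceiling=100.0
        )
        assert audit.certified

    def test_default_generator_certified(self):
        audit = audit_generator(n_sequences=2000, seed=1)
        assert audit.certified
        assert audit.max_mean_pct_correct <= 60.0
        assert len(audit.table) == 6 * 4

    def test_near_alternating_generator_not_certified(self):
        # a generator forced towards alternation is exploitable by win-shift,
        # which phase-locks onto the alternation after its first reward
        c = SequenceConstraints(
            max_run_length=11, alternation_band=(0.9, 1.0), max_side_imbalance=1
        )
        audit = audit_generator(
            constraints=c, session_lengths=[11], n_sequences=2000, seed=2
        )
        assert not audit.certified
        t = audit.table
        ws = t.loc[t["policy"] == "WIN_SHIFT", "mean_pct_correct"].item()
        assert ws > 60.0
        # exact mean over the enumerated accepted set (brute-force oracle)
        exact = np.mean(
            [
                simulate_strategy(
                    Policy.WIN_SHIFT, [Side(v) for v in seq], first_choice=fc
                ).percent_correct
                for seq in enumerate_valid_sequences(11, c)
                for fc in (L, R)
            ]
        )
        assert exact > 60.0
        assert ws == pytest.approx(exact, abs=2.0)

    def test_empty_lengths_rejected(self):
        with pytest.raises(ValueError):
            audit_generator(session_lengths=[])


class TestCompliance:
    def test_self_consistency_is_100(self):
        for policy in (Policy.WIN_STAY, Policy.WIN_SHIFT, Policy.SPONT_ALTERNATE):
            schedule = generate_sequence(20, seed=5).sides
            res = simulate_strategy(policy, schedule, first_choice=L)
            outcomes = [c is s for c, s in zip(res.per_trial_choices, schedule)]
            assert compliance(res.per_trial_choices, outcomes, policy) == 100.0

    def test_alternating_responses(self):
        responses = sides("LRLRLRLRLR")
        outcomes = [True] * 10
        assert compliance(responses, outcomes, Policy.SPONT_ALTERNATE) == 100.0
        # ALWAYS_LEFT predicts L on trials 2..10; responses there are RLRLRLRLR
        n_left = sum(r is L for r in responses[1:])
        assert compliance(responses, outcomes, Policy.ALWAYS_LEFT) == pytest.approx(
            100 * n_left / 9
        )

    def test_random_responses_near_half_against_deterministic_policy(self):
        rng = np.random.default_rng(12)
        responses = [Side(int(v)) for v in rng.integers(0, 2, 4000)]
        outcomes = list(rng.integers(0, 2, 4000).astype(bool))
        val = compliance(responses, outcomes, Policy.WIN_STAY)
        assert val == pytest.approx(50.0, abs=3.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compliance([L, R], [True], Policy.WIN_STAY)
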