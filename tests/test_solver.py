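"""Backward induction, policy evaluation, and the enumeration oracle."""

import copy

import numpy as np
import pytest

from stroke_mdp import (
    FittedMDP,
    Policy,
    RewardModel,
    TransitionModel,
    backward_induction,
    brute_force_optimal,
    evaluate_policy,
    policy_space_size,
    random_model,
)
from stroke_mdp.errors import EvaluationError, OracleError
from stroke_mdp.schemas import ActionSchema, StateSchema


def tiny_model(probs, mean, horizon, terminal=None):
    """Assemble a FittedMDP from explicit tables (expected rewards derived)."""
    expected = {
        t: {
            pair: sum(probs[t][pair][j] * mean[t][pair][j] for j in probs[t][pair])
            for pair in probs[t]
        }
        for t in probs
    }
    states = {i for t in probs for (i, _a) in probs[t]} | {
        j for t in probs for pair in probs[t] for j in probs[t][pair]
    }
    term = dict.fromkeys(states, 0.0)
    if terminal:
        term.update(terminal)
    return FittedMDP(
        state_schema=StateSchema(alphabets=(frozenset(range(10)),)),
        action_schema=ActionSchema(alphabets=(frozenset(range(10)),)),
        transitions=TransitionModel(probs=probs),
        rewards=RewardModel(mean=mean, expected=expected, terminal=term),
        horizon=horizon,
    )


class TestBackwardInduction:
    def test_single_stage_reduces_to_argmax(self):
        probs = {1: {("0", "0"): {"0": 1.0}, ("0", "1"): {"0": 1.0}}}
        mean = {1: {("0", "0"): {"0": 2.0}, ("0", "1"): {"0": 5.0}}}
        model = tiny_model(probs, mean, horizon=1)
        policy, values = backward_induction(model)
        assert policy.rules[1]["0"] == "1"
        assert values.values[1]["0"] == pytest.approx(5.0)

    def test_terminal_shift_is_additive(self):
        model = random_model(3, horizon=2)
        _p0, v0 = backward_induction(model)
        c = 2.5
        shifted = {s: c for s in model.states()}
        _p1, v1 = backward_induction(model, terminal=shifted)
        for t in (1, 2):
            for i, v in v0.values[t].items():
                assert v1.values[t][i] == pytest.approx(v + c, abs=1e-9)

    def test_deterministic_resolution(self):
        model = random_model(9, horizon=2)
        p1, v1 = backward_induction(model)
        p2, v2 = backward_induction(model)
        assert p1.rules == p2.rules and v1.values == v2.values

    def test_tie_break_prefers_smallest_action_code(self):
        probs = {1: {("0", "3"): {"0": 1.0}, ("0", "1"): {"0": 1.0}}}
        mean = {1: {("0", "3"): {"0": 4.0}, ("0", "1"): {"0": 4.0}}}
        model = tiny_model(probs, mean, horizon=1)
        policy, _ = backward_induction(model)
        assert policy.rules[1]["0"] == "1"


class TestEvaluatePolicy:
    def chain_model(self):
        # deterministic chain 0 -> 1 -> 2, stage rewards 2 then 3
        probs = {1: {("0", "0"): {"1": 1.0}, ("1", "0"): {"1": 1.0}},
                 2: {("1", "0"): {"2": 1.0}, ("0", "0"): {"0": 1.0}}}
        mean = {1: {("0", "0"): {"1": 2.0}, ("1", "0"): {"1": 0.0}},
                2: {("1", "0"): {"2": 3.0}, ("0", "0"): {"0": 0.0}}}
        return tiny_model(probs, mean, horizon=2)

    def test_hand_computed_chain(self):
        model = self.chain_model()
        policy = Policy(rules={1: {"0": "0", "1": "0"}, 2: {"1": "0", "0": "0"}})
        assert evaluate_policy(model, policy, "0") == pytest.approx(5.0)

    def test_all_zero_rewards_give_zero(self):
        model = self.chain_model()
        zeroed = copy.deepcopy(model)
        for t in zeroed.rewards.mean:
            for pair in zeroed.rewards.mean[t]:
                zeroed.rewards.mean[t][pair] = {
                    j: 0.0 for j in zeroed.rewards.mean[t][pair]
                }
                zeroed.rewards.expected[t][pair] = 0.0
        policy = Policy(rules={1: {"0": "0", "1": "0"}, 2: {"1": "0", "0": "0"}})
        assert evaluate_policy(zeroed, policy, "0") == 0.0

    def test_unsupported_initial_state_rejected(self):
        model = self.chain_model()
        policy = Policy(rules={1: {"0": "0", "1": "0"}, 2: {"1": "0", "0": "0"}})
        with pytest.raises(EvaluationError):
            evaluate_policy(model, policy, "9")

    def test_inadmissible_policy_rejected(self):
        model = self.chain_model()
        policy = Policy(rules={1: {"0": "7", "1": "0"}, 2: {"1": "0", "0": "0"}})
        with pytest.raises(EvaluationError):
            evaluate_policy(model, policy, "0")


class TestBruteForceOracle:
    def test_unique_policy_returned_when_no_choice(self):
        probs = {1: {("0", "2"): {"0": 1.0}}}
        mean = {1: {("0", "2"): {"0": 1.5}}}
        model = tiny_model(probs, mean, horizon=1)
        policy, values = brute_force_optimal(model)
        assert policy.rules == {1: {"0": "2"}}
        assert values.values[1]["0"] == pytest.approx(1.5)

    def test_policy_space_size_matches_combinatorics(self):
        model = random_model(12, horizon=2)
        expected = 1
        for t in model.stages():
            for _i, acts in model.admissible(t).items():
                expected *= len(acts)
        assert policy_space_size(model) == expected

    def test_cap_is_enforced(self):
        model = random_model(12, horizon=2)
        if policy_space_size(model) > 1:
            with pytest.raises(OracleError):
                brute_force_optimal(model, cap=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_backward_induction(self, seed):
        rng = np.random.default_rng(1000 + seed)
        horizon = int(rng.integers(2, 4))
        model = random_model(rng, max_states=5, max_actions=4, horizon=horizon)
        policy, values = backward_induction(model)
        _bf_policy, bf_values = brute_force_optimal(model)
        for i, v in bf_values.values[1].items():
            assert values.values[1][i] == pytest.approx(v, abs=1e-9)
            # the solved policy attains the enumerated maximum
            assert evaluate_policy(model, policy, i) == pytest.approx(v, abs=1e-9)

    def test_optimal_policy_dominates_alternatives(self):
        rng = np.random.default_rng(55)
        model = random_model(rng, max_states=4, max_actions=3, horizon=2)
        policy, values = backward_induction(model)
        # compare against a handful of perturbed admissible policies
        for _ in range(10):
            rules = {
                t: {
                    i: rng.choice(model.admissible(t)[i])
                    for i in model.stage_states(t)
                }
                for t in model.stages()
            }
            other = Policy(rules=rules)
            for i in values.values[1]:
                assert evaluate_policy(model, other, i) <= values.values[1][i] + 1e-9


def test_increasing_a_reward_never_decreases_values():
    model = random_model(8, horizon=2)
    _p, base = backward_induction(model)
    bumped = copy.deepcopy(model)
    t = 2
    pair = sorted(bumped.rewards.mean[t])[0]
    j = sorted(bumped.rewards.mean[t][pair])[0]
    bumped.rewards.mean[t][pair][j] += 4.0
    bumped.rewards.expected[t][pair] = sum(
        bumped.transitions.probs[t][pair][k] * bumped.rewards.mean[t][pair][k]
        for k in bumped.transitions.probs[t][pair]
    )
    _p2, new = backward_induction(bumped)
    for stage in (1, 2):
        for i, v in base.values[stage].items():
            assert new.values[stage][i] >= v - 1e-12
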