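"""The synthetic cohort generator and its exact ground truth."""

import dataclasses
import math

import numpy as np
import pytest

from stroke_mdp import (
    apply_missingness,
    backward_induction,
    build_episodes,
    default_cohort_spec,
    designated_recovery,
    fit_mdp,
    generate_cohort,
    ground_truth_mdp,
    load_cohort_spec,
    plant_effect_gap,
    recovery_cohort_spec,
    save_cohort_spec,
)
from stroke_mdp.errors import ValidationError


def binom_ci99(p, n):
    half = 2.576 * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


def max_transition_error(model, truth, min_true_p=0.05):
    worst = 0.0
    for t in model.stages():
        for pair in model.transitions.pairs(t):
            true_row = truth.model.transitions.probs[t].get(pair)
            assert true_row is not None, f"fitted pair {pair} unknown to the truth"
            fit_row = model.transitions.probs[t][pair]
            for j, p in true_row.items():
                if p >= min_true_p:
                    worst = max(worst, abs(fit_row.get(j, 0.0) - p))
    return worst


class TestGeneration:
    def test_patient_count(self):
        records, _ = generate_cohort(default_cohort_spec(n_patients=960, seed=1))
        assert len(records) == 960

    def test_identical_seed_is_bit_identical(self):
        spec = default_cohort_spec(n_patients=200, seed=12)
        a, truth_a = generate_cohort(spec)
        b, truth_b = generate_cohort(spec)
        assert a == b
        assert truth_a.model.transitions.probs == truth_b.model.transitions.probs
        assert truth_a.policy.rules == truth_b.policy.rules

    def test_admission_marginals_match_reference_composition(self):
        spec = dataclasses.replace(default_cohort_spec(n_patients=50_000, seed=31), missingness={})
        records, _ = generate_cohort(spec)
        share_old = sum(r.characteristics["i1"] == 3 for r in records) / len(records)
        lo, hi = binom_ci99(652 / 960, len(records))
        assert lo <= share_old <= hi
        share_yin = sum(r.characteristics["i5"] == 2 for r in records) / len(records)
        lo, hi = binom_ci99(601 / 960, len(records))
        assert lo <= share_yin <= hi

    def test_death_is_absorbing_with_maximal_score(self, score_schema):
        spec = default_cohort_spec(n_patients=2000, seed=6)
        spec = dataclasses.replace(
            spec,
            death=dataclasses.replace(
                spec.death,
                stage1_by_level=(0.05,) * 5,
                stage2_by_level=(0.05,) * 5,
            ),
            missingness={},
        )
        records, _ = generate_cohort(spec)
        n_dead = 0
        for r in records:
            for t in (1, 2, 3):
                if r.death[t]:
                    n_dead += 1
                    assert all(r.death[u] for u in (1, 2, 3) if u >= t)
                    assert sum(r.item_scores[t].values()) == 29
                    break
            if r.death[2]:
                assert r.actions[2] == (0, 0, 0, 0, 0)
        assert n_dead > 0, "death probability 0.05 produced no deaths"


class TestMissingness:
    def test_zero_rates_change_nothing(self, score_schema):
        spec = dataclasses.replace(default_cohort_spec(n_patients=50, seed=2), missingness={})
        records, _ = generate_cohort(spec)
        masked, mask = apply_missingness(records, {"ataxia": 0.0}, seed=1)
        assert masked == records and mask == []

    def test_rate_one_masks_everything(self):
        spec = dataclasses.replace(default_cohort_spec(n_patients=30, seed=2), missingness={})
        records, _ = generate_cohort(spec)
        masked, _ = apply_missingness(records, {"ataxia": 1.0}, seed=1)
        assert all(
            r.item_scores[t]["ataxia"] is None for r in masked for t in (1, 2, 3)
        )

    def test_empirical_rate_matches_reference(self):
        spec = dataclasses.replace(default_cohort_spec(n_patients=3334, seed=8), missingness={})
        records, _ = generate_cohort(spec)
        masked, mask = apply_missingness(records, {"ataxia": 0.1839}, seed=3)
        n_cells = 3 * len(records)
        frac = len(mask) / n_cells
        lo, hi = binom_ci99(0.1839, n_cells)
        assert lo <= frac <= hi

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            apply_missingness([], {"ataxia": 1.2}, seed=0)


class TestGroundTruthConsistency:
    def test_fit_converges_to_truth(self, score_schema):
        errs = {}
        for n in (2000, 20_000):
            spec = recovery_cohort_spec(n_patients=n, seed=44)
            records, truth = generate_cohort(spec)
            episodes, _ = build_episodes(records, spec.score_schema)
            model, _ = fit_mdp(episodes, min_count=10)
            errs[n] = max_transition_error(model, truth)
        assert errs[20_000] < errs[2000]
        assert errs[20_000] < 0.02

    def test_truth_rows_are_stochastic(self):
        truth = ground_truth_mdp(recovery_cohort_spec(n_patients=10, seed=0))
        for t in (1, 2):
            for pair, row in truth.model.transitions.probs[t].items():
                assert abs(sum(row.values()) - 1.0) <= 1e-12
                assert all(p >= 0 for p in row.values())

    def test_expected_rewards_within_score_range(self):
        truth = ground_truth_mdp(default_cohort_spec(n_patients=10, seed=0))
        for t in (1, 2):
            for pair, u in truth.model.rewards.expected[t].items():
                assert -29.0 <= u <= 29.0


class TestEffectPlanting:
    def test_zero_gap_is_identity(self):
        spec = default_cohort_spec(n_patients=100, seed=0)
        assert plant_effect_gap(spec, 0.0) is spec

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            plant_effect_gap(default_cohort_spec(n_patients=100), -1.0)

    def test_unreachable_gap_rejected(self):
        with pytest.raises(ValidationError, match="not achievable"):
            plant_effect_gap(default_cohort_spec(n_patients=100), 40.0)

    def test_truth_optimum_is_the_designated_action(self):
        spec = dataclasses.replace(default_cohort_spec(n_patients=100, seed=0), missingness={})
        planted = plant_effect_gap(spec, 3.0)
        truth = ground_truth_mdp(planted)
        for t in (1, 2):
            for i in truth.model.stage_states(t):
                if i.endswith("5"):
                    continue  # maximal severity: separability capped by score range
                assert truth.policy.rules[t][i] == truth.designated[i], (t, i)

    def test_planted_effect_recovered_end_to_end(self):
        spec = dataclasses.replace(default_cohort_spec(n_patients=8000, seed=15), missingness={})
        planted = plant_effect_gap(spec, 3.0)
        records, truth = generate_cohort(planted)
        episodes, _ = build_episodes(records, planted.score_schema)
        model, _ = fit_mdp(episodes, min_count=10)
        policy, values = backward_induction(model)
        frac, eligible, _mism = designated_recovery(model, values, truth, min_support=50)
        assert eligible >= 10
        assert frac >= 0.95


class TestImputationRobustness:
    def test_policy_stable_under_moderate_missingness(self, score_schema):
        from stroke_mdp import impute_cohort

        spec = dataclasses.replace(default_cohort_spec(n_patients=6000, seed=23), missingness={})
        planted = plant_effect_gap(spec, 3.0)
        records, _ = generate_cohort(planted)

        def solve_policy(recs):
            recs, _ = impute_cohort(recs, planted.score_schema)
            episodes, _ = build_episodes(recs, planted.score_schema)
            model, _ = fit_mdp(episodes, min_count=10)
            policy, _values = backward_induction(model)
            return policy

        clean = solve_policy([dataclasses.replace(r) for r in records])
        masked, _ = apply_missingness(
            records, {"ataxia": 0.20, "visual_field": 0.20}, seed=99
        )
        noisy = solve_policy(masked)
        common = diffs = 0
        for t in (1, 2):
            for i, a in clean.rules[t].items():
                if i in noisy.rules[t]:
                    common += 1
                    diffs += noisy.rules[t][i] != a
        assert common > 0
        assert diffs / common <= 0.10


def test_spec_yaml_round_trip(tmp_path):
    spec = default_cohort_spec(n_patients=123, seed=42)
    path = tmp_path / "spec.yaml"
    save_cohort_spec(spec, path)
    back = load_cohort_spec(path)
    assert back == spec
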