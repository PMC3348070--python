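"""Synthetic stroke-cohort generator with an exactly known ground truth.

The generator emulates the statistical structure the estimation pipeline
assumes: a hospital cohort whose admission composition follows configurable
marginals (defaults reproduce the reference cohort: 652/960 aged over 66,
601/960 Yin pattern, severity concentrated in levels 1-3, ...), whose
treatment flags follow a probabilistic rendering of the intervention-
assignment tendencies (pattern-matched TCM treatments, bowel-relaxing
treatment for constipated patients, near-universal antiplatelet agents and
herbal medicine), and whose outcomes follow a per-(state, action) latent
score-change model with death as an absorbing maximal score.

Ground truth
------------
The severity level (the ``i6`` state digit) must evolve as a Markov chain
with a kernel we can write down, otherwise "does the pipeline recover the
truth?" has no exact answer.  Two design choices guarantee this:

* the latent score change is drawn from a *discretized Gaussian* truncated
  at +-6 sigma — the exact finite distribution the analytic kernel
  integrates over; and
* after the latent change selects the next severity level, the realized
  score is re-drawn uniformly within the destination band, so the
  within-band score distribution is uniform at every timepoint regardless
  of history.

The per-(state, action) level kernel, per-transition expected rewards and
the optimal policy of the implied two-stage MDP are then computed exactly
(:func:`ground_truth_mdp`) and serve as the estimand in recovery tests.

``plant_effect_gap`` additionally separates one designated action per
state from all alternatives by at least a requested value gap (by
penalising the alternatives' outcome means — downward room in the score
range always exists, upward room does not), which turns optimal-policy
recovery into a checkable property.
"""

from __future__ import annotations

import copy
import dataclasses
import datetime
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import ndtr

from .cohort import PatientRecord, STAGES, TIMEPOINTS
from .errors import ValidationError
from .estimation import FittedMDP, RewardModel, TransitionModel
from .schemas import (
    ActionSchema,
    ScoreSchema,
    StateSchema,
    default_action_schema,
    default_score_schema,
    default_state_schema,
    level_band,
    level_band_midpoint,
    score_to_level,
)
from .solve import Policy, ValueFunction, backward_induction

__all__ = [
    "StateMarginals",
    "AssignmentRules",
    "OutcomeModel",
    "DeathModel",
    "CohortSpec",
    "GroundTruthMDP",
    "default_cohort_spec",
    "recovery_cohort_spec",
    "designated_action",
    "generate_cohort",
    "ground_truth_mdp",
    "plant_effect_gap",
    "apply_missingness",
    "designated_recovery",
    "save_cohort_spec",
    "load_cohort_spec",
]

_DEAD_ACTION = "00000"


def _check_dist(name: str, dist: Mapping[int, float]) -> None:
    if not dist:
        raise ValidationError(f"{name}: empty distribution")
    if any(p < 0 or p > 1 for p in dist.values()):
        raise ValidationError(f"{name}: probabilities must lie in [0, 1]")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class StateMarginals:
    """Admission-time category probabilities for each state component."""

    i1: dict[int, float]
    i2: dict[int, float]
    i3: dict[int, float]
    i4: dict[int, float]
    i5: dict[int, float]
    i6: dict[int, float]

    def validate(self) -> None:
        for name in ("i1", "i2", "i3", "i4", "i5", "i6"):
            _check_dist(name, getattr(self, name))


@dataclass(frozen=True)
class AssignmentRules:
    """Probabilistic treatment-assignment tendencies.

    Pattern-matched TCM treatments (Yi Qi Wen Yang for the Yin pattern,
    Qing Re Xi Feng for the Yang pattern) are likely; bowel-relaxing
    treatment tracks a persistent latent constipation indicator;
    antiplatelet/anticoagulant agents and herbal medicine are
    near-universal with small exception rates.  The exception rates are not
    quantified in the source setting and are documented package defaults.
    """

    p_a1: float = 0.92
    p_a2_matched: float = 0.85  # i5 == 2 (Yin)
    p_a2_other: float = 0.10
    p_a3_matched: float = 0.85  # i5 == 1 (Yang)
    p_a3_other: float = 0.10
    p_a4_constipated: float = 0.90
    p_a4_other: float = 0.08
    p_a5: float = 0.95
    constipation_rate: float = 0.30

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"assignment rule {f.name}={v} outside [0, 1]")

    def flag_probs(self, i5: int, constipated: bool) -> tuple[float, ...]:
        return (
            self.p_a1,
            self.p_a2_matched if i5 == 2 else self.p_a2_other,
            self.p_a3_matched if i5 == 1 else self.p_a3_other,
            self.p_a4_constipated if constipated else self.p_a4_other,
            self.p_a5,
        )


def designated_action(components: Sequence[int]) -> tuple[int, ...]:
    """The pattern-concordant reference action used for effect planting.

    Antiplatelet agents and herbal medicine, plus the TCM treatment
    matching the patient's pattern (Yi Qi Wen Yang for Yin, Qing Re Xi Feng
    for Yang), without bowel-relaxing treatment.
    """
    i5 = components[4]
    return (1, int(i5 == 2), int(i5 == 1), 0, 1)


@dataclass(frozen=True)
class OutcomeModel:
    """Latent per-(state, action) score-change model.

    The latent change ``d`` (positive = improvement) is a discretized
    Gaussian with mean ``mu(state, action)`` and a per-level standard
    deviation; the new score is ``clip(score - d, 0, 29)``.  The mean is a
    per-level baseline plus bonuses for pattern-matched TCM treatment,
    antiplatelet agents and herbal medicine, minus a penalty for
    pattern-mismatched TCM treatment.  ``nondesignated_penalty`` (set by
    :func:`plant_effect_gap`) additionally lowers the mean of every action
    other than the designated one.
    """

    base_mean_by_level: tuple[float, ...] = (0.5, 1.2, 2.2, 3.0, 3.2)
    matched_bonus: float = 0.8
    mismatched_penalty: float = 0.3
    a1_bonus: float = 0.5
    a5_bonus: float = 0.4
    sigma_by_level: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0, 2.0)
    nondesignated_penalty: float = 0.0

    def validate(self) -> None:
        if len(self.base_mean_by_level) != 5 or len(self.sigma_by_level) != 5:
            raise ValidationError("outcome model needs 5 per-level entries")
        if any(s < 0.1 for s in self.sigma_by_level):
            raise ValidationError("outcome noise sigma must be >= 0.1")
        if self.nondesignated_penalty < 0:
            raise ValidationError("nondesignated_penalty must be >= 0")

    def mean_change(self, components: Sequence[int], flags: Sequence[int]) -> float:
        i5, level = components[4], components[5]
        a1, a2, a3, _a4, a5 = flags
        mu = self.base_mean_by_level[level - 1]
        if (i5 == 2 and a2) or (i5 == 1 and a3):
            mu += self.matched_bonus
        if (i5 == 1 and a2) or (i5 == 2 and a3):
            mu -= self.mismatched_penalty
        mu += self.a1_bonus * a1 + self.a5_bonus * a5
        if self.nondesignated_penalty and tuple(flags) != designated_action(components):
            mu -= self.nondesignated_penalty
        return mu

    def sigma(self, level: int) -> float:
        return self.sigma_by_level[level - 1]


@dataclass(frozen=True)
class DeathModel:
    """Per-stage, per-level probability of transition to the death score."""

    stage1_by_level: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    stage2_by_level: tuple[float, ...] = (0.0, 0.004, 0.012, 0.03, 0.05)

    def validate(self) -> None:
        for probs in (self.stage1_by_level, self.stage2_by_level):
            if len(probs) != 5 or any(not (0 <= p <= 1) for p in probs):
                raise ValidationError("death model needs 5 per-level probabilities in [0,1]")

    def prob(self, stage: int, level: int) -> float:
        probs = self.stage1_by_level if stage == 1 else self.stage2_by_level
        return probs[level - 1]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort and its ground truth."""

    n_patients: int
    marginals: StateMarginals
    rules: AssignmentRules = field(default_factory=AssignmentRules)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    death: DeathModel = field(default_factory=DeathModel)
    missingness: dict[str, float] = field(default_factory=dict)
    score_schema: ScoreSchema = field(default_factory=default_score_schema)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        self.marginals.validate()
        self.rules.validate()
        self.outcome.validate()
        self.death.validate()
        for item, rate in self.missingness.items():
            if item not in self.score_schema.item_max:
                raise ValidationError(f"missingness rate for unknown item {item!r}")
            if not (0 <= rate <= 1):
                raise ValidationError(f"missingness rate for {item!r} outside [0, 1]")


#: Per-item missingness rates matching the reference cohort's reported
#: ranges (ataxia 18.39%, visual field 13.80%, sensory 13.76%, the rest
#: between 0.07% and 7.11%).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "ataxia": 0.1839,
    "visual_field": 0.1380,
    "sensory": 0.1376,
    "consciousness": 0.0007,
    "facial_paralysis": 0.02,
    "upper_limb": 0.03,
    "lower_limb": 0.03,
    "aphasia": 0.05,
    "dysarthria": 0.0711,
}


def default_cohort_spec(n_patients: int = 960, seed: int = 0) -> CohortSpec:
    """Cohort with the reference admission composition.

    Marginals are the observed admission proportions: age 46-65 vs >66 =
    308/652 of 960; disease history 252 none / 708 at least one;
    complications 18/960; all patients with the channels/collaterals TCM
    diagnosis; patterns Yang/Yin/composite/other = 305/601/38/16; severity
    levels 1-3 = 402/355/203 (no level 4/5 admissions).
    """
    marginals = StateMarginals(
        i1={2: 308 / 960, 3: 652 / 960},
        i2={0: 252 / 960, 1: 708 / 960},
        i3={0: 942 / 960, 1: 18 / 960},
        i4={1: 1.0},
        i5={1: 305 / 960, 2: 601 / 960, 3: 38 / 960, 4: 16 / 960},
        i6={1: 402 / 960, 2: 355 / 960, 3: 203 / 960},
    )
    return CohortSpec(
        n_patients=n_patients,
        marginals=marginals,
        missingness=dict(DEFAULT_MISSINGNESS),
        seed=seed,
    )


def recovery_cohort_spec(n_patients: int = 50_000, seed: int = 0) -> CohortSpec:
    """Concentrated-support cohort for transition-recovery checks.

    A single demographic stratum (elderly, with history, no complications,
    Yin pattern) with three admission severity levels and exactly two
    treatment arms (with/without Yi Qi Wen Yang), so that every
    (state, action) cell carries thousands of episodes and empirical
    frequencies are tight around the truth.  Outcome-noise truncation keeps
    the severity set {1, 2, 3} closed, so no thin boundary states appear.
    """
    marginals = StateMarginals(
        i1={3: 1.0},
        i2={1: 1.0},
        i3={0: 1.0},
        i4={1: 1.0},
        i5={2: 1.0},
        i6={1: 0.25, 2: 0.30, 3: 0.45},
    )
    rules = AssignmentRules(
        p_a1=1.0,
        p_a2_matched=0.5,
        p_a2_other=0.5,
        p_a3_matched=0.0,
        p_a3_other=0.0,
        p_a4_constipated=0.0,
        p_a4_other=0.0,
        p_a5=1.0,
        constipation_rate=0.0,
    )
    outcome = OutcomeModel(
        base_mean_by_level=(0.0, 0.0, 2.0, 0.0, 0.0),
        matched_bonus=0.5,
        mismatched_penalty=0.0,
        a1_bonus=0.0,
        a5_bonus=0.0,
        sigma_by_level=(0.5, 0.5, 0.4, 0.5, 0.5),
    )
    death = DeathModel(
        stage1_by_level=(0.0,) * 5, stage2_by_level=(0.0,) * 5
    )
    return CohortSpec(
        n_patients=n_patients,
        marginals=marginals,
        rules=rules,
        outcome=outcome,
        death=death,
        missingness={},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact kernels


@lru_cache(maxsize=4096)
def _discretized_gaussian(mu: float, sigma: float) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Integer support and probabilities of round(N(mu, sigma)), +-6 sigma."""
    lo = math.ceil(mu - 6 * sigma)
    hi = math.floor(mu + 6 * sigma)
    if hi < lo:
        hi = lo = round(mu)
    support = np.arange(lo, hi + 1)
    upper = ndtr((support + 0.5 - mu) / sigma)
    lower = ndtr((support - 0.5 - mu) / sigma)
    probs = upper - lower
    probs /= probs.sum()
    return tuple(int(d) for d in support), tuple(float(p) for p in probs)


@lru_cache(maxsize=4096)
def _level_kernel(
    level: int, mu: float, sigma: float, p_death: float
) -> tuple[dict[int | str, float], dict[int | str, float]]:
    """Exact next-level distribution and conditional mean rewards.

    Returns ``(probs, mean_rewards)`` keyed by next level 1..5 and the
    sentinel ``"death"``.  Marginalizes the uniform within-band score and
    the discretized-Gaussian change; the reward of an alive transition uses
    the uniform re-draw within the destination band (``E[s|j] - mid_j``),
    the reward of death is ``mid_level - 29``.
    """
    lo, hi = level_band(level)
    band = range(lo, hi + 1)
    w_s = 1.0 / len(band)
    support, d_probs = _discretized_gaussian(mu, sigma)
    alive_mass: dict[int, float] = defaultdict(float)
    alive_s_sum: dict[int, float] = defaultdict(float)
    for s in band:
        for d, pd_ in zip(support, d_probs):
            s_next = min(max(s - d, 0), 29)
            j = score_to_level(s_next)
            alive_mass[j] += w_s * pd_
            alive_s_sum[j] += w_s * pd_ * s
    probs: dict[int | str, float] = {}
    rewards: dict[int | str, float] = {}
    for j, mass in sorted(alive_mass.items()):
        if mass <= 0:
            continue
        probs[j] = (1.0 - p_death) * mass
        rewards[j] = alive_s_sum[j] / mass - level_band_midpoint(j)
    if p_death > 0:
        probs["death"] = p_death
        rewards["death"] = level_band_midpoint(level) - 29.0
    return dict(probs), dict(rewards)


@dataclass
class GroundTruthMDP:
    """The generator's implied MDP, its optimal solution, and the
    per-state designated action used by effect planting."""

    model: FittedMDP
    policy: Policy
    values: ValueFunction
    designated: dict[str, str]


def _core_combos(marginals: StateMarginals) -> list[tuple[tuple[int, ...], float]]:
    """All (i1..i5) combinations with positive admission probability."""
    combos: list[tuple[tuple[int, ...], float]] = []
    axes = [
        sorted((k, p) for k, p in getattr(marginals, name).items() if p > 0)
        for name in ("i1", "i2", "i3", "i4", "i5")
    ]
    def rec(idx: int, prefix: tuple[int, ...], prob: float):
        if idx == len(axes):
            combos.append((prefix, prob))
            return
        for k, p in axes[idx]:
            rec(idx + 1, prefix + (k,), prob * p)
    rec(0, (), 1.0)
    return combos


def _positive_actions(rules: AssignmentRules, i5: int) -> list[tuple[int, ...]]:
    """Action vectors with positive assignment probability for a pattern.

    The generator never assigns the all-zero combination to a living
    patient (herbal medicine is forced on instead), so it is excluded here;
    it is reserved for the absorbing death state.
    """
    per_flag: list[list[int]] = []
    for k, p in enumerate(rules.flag_probs(i5, constipated=True)):
        p2 = rules.flag_probs(i5, constipated=False)[k]
        vals = set()
        for q in (p, p2):
            if q > 0:
                vals.add(1)
            if q < 1:
                vals.add(0)
        per_flag.append(sorted(vals))
    out: list[tuple[int, ...]] = []
    def rec(idx: int, prefix: tuple[int, ...]):
        if idx == 5:
            if any(prefix):
                out.append(prefix)
            return
        for v in per_flag[idx]:
            rec(idx + 1, prefix + (v,))
    rec(0, ())
    return out


def ground_truth_mdp(spec: CohortSpec) -> GroundTruthMDP:
    """Exact two-stage MDP implied by a cohort specification.

    States are every demographic combination with positive admission
    probability crossed with all five severity levels (the kernel is
    defined for every level, reachable or not); admissible actions are all
    combinations with positive assignment probability, plus the all-zero
    combination for the absorbing maximal-severity (death) state.
    """
    spec.validate()
    state_schema = default_state_schema()
    action_schema = default_action_schema()
    combos = _core_combos(spec.marginals)
    probs: dict[int, dict[tuple[str, str], dict[str, float]]] = {1: {}, 2: {}}
    mean: dict[int, dict[tuple[str, str], dict[str, float]]] = {1: {}, 2: {}}
    expected: dict[int, dict[tuple[str, str], float]] = {1: {}, 2: {}}
    designated: dict[str, str] = {}

    for combo, _p in combos:
        actions = _positive_actions(spec.rules, combo[4])
        for level in range(1, 6):
            comps = combo + (level,)
            i_code = state_schema.encode(comps)
            designated[i_code] = action_schema.encode(designated_action(comps))
            death_code = state_schema.encode(combo + (5,))
            for stage in STAGES:
                if level == 5:
                    # absorbing: the all-zero action of the dead
                    pair = (i_code, _DEAD_ACTION)
                    probs[stage][pair] = {i_code: 1.0}
                    mean[stage][pair] = {i_code: 0.0}
                    expected[stage][pair] = 0.0
                for flags in actions:
                    a_code = action_schema.encode(flags)
                    mu = spec.outcome.mean_change(comps, flags)
                    kern, krew = _level_kernel(
                        level,
                        round(mu, 9),
                        spec.outcome.sigma(level),
                        spec.death.prob(stage, level),
                    )
                    prow: dict[str, float] = defaultdict(float)
                    usum: dict[str, float] = defaultdict(float)
                    for j, p in kern.items():
                        j_code = death_code if j == "death" else state_schema.encode(combo + (j,))
                        prow[j_code] += p
                        usum[j_code] += p * krew[j]
                    pair = (i_code, a_code)
                    probs[stage][pair] = dict(prow)
                    mean[stage][pair] = {j: usum[j] / prow[j] for j in prow}
                    expected[stage][pair] = sum(usum.values())

    states = {i for stage_tab in probs.values() for (i, _a) in stage_tab}
    model = FittedMDP(
        state_schema=state_schema,
        action_schema=action_schema,
        transitions=TransitionModel(probs=probs),
        rewards=RewardModel(
            mean=mean, expected=expected, terminal={s: 0.0 for s in states}
        ),
        horizon=2,
    )
    policy, values = backward_induction(model)
    return GroundTruthMDP(model=model, policy=policy, values=values, designated=designated)


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_categorical(rng: np.random.Generator, dist: Mapping[int, float], n: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    p = np.array([dist[k] for k in sorted(dist)])
    return rng.choice(keys, size=n, p=p / p.sum())


_BAND_LO = np.array([0, 3, 6, 13, 20])
_BAND_HI = np.array([2, 5, 12, 19, 29])


def _levels_of(scores: np.ndarray) -> np.ndarray:
    return np.digitize(scores, [3, 6, 13, 20]) + 1


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[PatientRecord], GroundTruthMDP]:
    """Generate a cohort and the ground truth it was drawn from.

    A single root seed (``seed`` or ``spec.seed``) drives independent
    substreams for demographics, treatment assignment, outcomes, item
    allocation and missingness, so each aspect is reproducible in
    isolation.  Identical spec and seed give bit-identical output.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    demo_rng, assign_rng, outcome_rng, item_rng, miss_rng = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    n = spec.n_patients
    truth = ground_truth_mdp(spec)

    m = spec.marginals
    comps = np.column_stack([
        _draw_categorical(demo_rng, m.i1, n),
        _draw_categorical(demo_rng, m.i2, n),
        _draw_categorical(demo_rng, m.i3, n),
        _draw_categorical(demo_rng, m.i4, n),
        _draw_categorical(demo_rng, m.i5, n),
    ])
    level = _draw_categorical(demo_rng, m.i6, n)
    lo, hi = _BAND_LO[level - 1], _BAND_HI[level - 1]
    score = lo + demo_rng.integers(0, hi - lo + 1)
    constipated = assign_rng.random(n) < spec.rules.constipation_rate

    scores = {1: score.astype(int)}
    dead = {1: np.zeros(n, dtype=bool)}
    actions: dict[int, np.ndarray] = {}
    levels = {1: level.astype(int)}

    for stage in STAGES:
        cur_level = levels[stage]
        cur_score = scores[stage]
        cur_dead = dead[stage]

        # treatment flags (never all-zero for the living; dead get all-zero)
        pmat = np.empty((n, 5))
        i5 = comps[:, 4]
        pmat[:, 0] = spec.rules.p_a1
        pmat[:, 1] = np.where(i5 == 2, spec.rules.p_a2_matched, spec.rules.p_a2_other)
        pmat[:, 2] = np.where(i5 == 1, spec.rules.p_a3_matched, spec.rules.p_a3_other)
        pmat[:, 3] = np.where(constipated, spec.rules.p_a4_constipated, spec.rules.p_a4_other)
        pmat[:, 4] = spec.rules.p_a5
        flags = (assign_rng.random((n, 5)) < pmat).astype(int)
        all_zero = flags.sum(axis=1) == 0
        flags[all_zero, 4] = 1
        flags[cur_dead] = 0
        actions[stage] = flags

        # latent change, death, next level and score
        mu = np.empty(n)
        sigma = np.empty(n)
        pdeath = np.empty(n)
        for idx in range(n):
            c = (*comps[idx], int(cur_level[idx]))
            mu[idx] = spec.outcome.mean_change(c, flags[idx])
            sigma[idx] = spec.outcome.sigma(int(cur_level[idx]))
            pdeath[idx] = spec.death.prob(stage, int(cur_level[idx]))
        mu = np.round(mu, 9)

        dies = (outcome_rng.random(n) < pdeath) & ~cur_dead
        d = np.zeros(n, dtype=int)
        keys = np.unique(np.column_stack([mu, sigma]), axis=0)
        for mu_k, sigma_k in keys:
            mask = (mu == mu_k) & (sigma == sigma_k) & ~cur_dead
            if not mask.any():
                continue
            support, pvec = _discretized_gaussian(float(mu_k), float(sigma_k))
            d[mask] = outcome_rng.choice(np.array(support), size=int(mask.sum()), p=np.array(pvec))

        raw = np.clip(cur_score - d, 0, 29)
        next_level = _levels_of(raw)
        nlo, nhi = _BAND_LO[next_level - 1], _BAND_HI[next_level - 1]
        next_score = nlo + outcome_rng.integers(0, nhi - nlo + 1)

        next_dead = cur_dead | dies
        next_score = np.where(next_dead, 29, next_score)
        next_level = np.where(next_dead, 5, next_level)
        scores[stage + 1] = next_score.astype(int)
        levels[stage + 1] = next_level.astype(int)
        dead[stage + 1] = next_dead

    # item-level scores: allocate each total uniformly across item pools
    item_max = [spec.score_schema.item_max[i] for i in spec.score_schema.item_names]
    names = spec.score_schema.item_names
    start = datetime.date(2005, 5, 1)
    records: list[PatientRecord] = []
    for idx in range(n):
        item_scores: dict[int, dict[str, int | None]] = {}
        for t in TIMEPOINTS:
            if dead[t][idx]:
                alloc = item_max
            else:
                alloc = item_rng.multivariate_hypergeometric(item_max, int(scores[t][idx]))
            item_scores[t] = {name: int(v) for name, v in zip(names, alloc)}
        records.append(
            PatientRecord(
                record_id=f"P{idx + 1:06d}",
                admission_date=(start + datetime.timedelta(days=idx % 1188)).isoformat(),
                characteristics={f"i{k + 1}": int(comps[idx, k]) for k in range(5)},
                item_scores=item_scores,
                death={t: bool(dead[t][idx]) for t in TIMEPOINTS},
                actions={s: tuple(int(v) for v in actions[s][idx]) for s in STAGES},
            )
        )

    if any(rate > 0 for rate in spec.missingness.values()):
        records, _mask = apply_missingness(
            records, spec.missingness, rng=miss_rng, in_place=True
        )
    return records, truth


def apply_missingness(
    records: Sequence[PatientRecord],
    rates: Mapping[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    in_place: bool = False,
) -> tuple[list[PatientRecord], list[tuple[str, int, str]]]:
    """Independently mask item values with per-item probabilities.

    Returns the (copied unless ``in_place``) records and the list of
    masked cells ``(record_id, timepoint, item)`` so a truth comparison can
    recover exactly what was hidden.
    """
    for item, rate in rates.items():
        if not (0 <= rate <= 1):
            raise ValidationError(f"missingness rate for {item!r} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    out = list(records) if in_place else copy.deepcopy(list(records))
    mask: list[tuple[str, int, str]] = []
    for item, rate in sorted(rates.items()):
        if rate == 0:
            continue
        draws = rng.random((len(out), len(TIMEPOINTS)))
        for ridx, record in enumerate(out):
            for tidx, t in enumerate(TIMEPOINTS):
                if draws[ridx, tidx] < rate and record.item_scores[t].get(item) is not None:
                    record.item_scores[t][item] = None
                    mask.append((record.record_id, t, item))
    return out, mask


# ---------------------------------------------------------------------------
# Effect planting and recovery measurement


def _min_q_gap(truth: GroundTruthMDP) -> float:
    """Smallest (over stages and treatable states) lead of the designated
    action's Q-value over the best alternative.

    Maximal-severity (level 5) states are excluded: from the top score
    band outcomes can hardly worsen, so no outcome-mean penalty can
    separate actions by an arbitrary value gap there; those states are
    also the ones with essentially no treatable support.
    """
    model = truth.model
    gap = math.inf
    for t in model.stages():
        cont = truth.values.values[t + 1]
        admissible = model.admissible(t)
        for i in sorted(model.stage_states(t)):
            if i.endswith("5"):
                continue
            a_star = truth.designated[i]
            if a_star not in admissible.get(i, ()):
                continue
            def q(a: str) -> float:
                val = model.expected_reward(t, i, a)
                for j, p in model.transitions.row(t, i, a).items():
                    val += p * cont.get(j, 0.0)
                return val
            rivals = [q(a) for a in admissible[i] if a not in (a_star, _DEAD_ACTION)]
            if rivals:
                gap = min(gap, q(a_star) - max(rivals))
    return gap


def plant_effect_gap(spec: CohortSpec, gap: float) -> CohortSpec:
    """Separate the designated action's true value from all alternatives.

    Returns a spec whose outcome model penalises every non-designated
    action just enough that, in the exact ground truth, the designated
    action's Q-value leads every alternative by at least ``gap`` score
    units at every stage and state.  ``gap=0`` returns the spec unchanged.
    Raises :class:`ValidationError` if no penalty within the score range
    can achieve the gap (the score floor/ceiling caps separability).
    """
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    if gap == 0:
        return spec
    penalty = float(gap)
    while penalty <= 29.0:
        candidate = replace(spec, outcome=replace(spec.outcome, nondesignated_penalty=penalty))
        if _min_q_gap(ground_truth_mdp(candidate)) >= gap:
            return candidate
        penalty *= 1.4
    raise ValidationError(
        f"effect gap {gap} not achievable: required penalty would push scores outside [0, 29]"
    )


def designated_recovery(
    model: FittedMDP,
    values: ValueFunction,
    truth: GroundTruthMDP,
    min_support: int = 50,
) -> tuple[float, int, list[tuple[int, str]]]:
    """Fraction of well-supported states whose fitted argmax is the
    designated action.

    A (stage, state) counts when the designated action has at least
    ``min_support`` episodes there; the comparison argmax runs over
    actions with that much support (thinly observed alternatives carry too
    much estimation noise to be meaningfully compared).  Returns
    ``(fraction, n_eligible, mismatches)``.
    """
    from .solve import support_restricted_policy

    restricted = support_restricted_policy(model, values, min_support)
    hits, eligible = 0, 0
    mismatches: list[tuple[int, str]] = []
    for t in model.stages():
        support = model.pair_support(t)
        for i in sorted(model.stage_states(t)):
            a_star = truth.designated.get(i)
            if a_star is None or support[(i, a_star)] < min_support:
                continue
            eligible += 1
            if restricted.rules[t].get(i) == a_star:
                hits += 1
            else:
                mismatches.append((t, i))
    fraction = hits / eligible if eligible else float("nan")
    return fraction, eligible, mismatches


# ---------------------------------------------------------------------------
# YAML (de)serialization of cohort specs


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    doc = {
        "n_patients": spec.n_patients,
        "seed": spec.seed,
        "marginals": {
            name: {int(k): float(v) for k, v in getattr(spec.marginals, name).items()}
            for name in ("i1", "i2", "i3", "i4", "i5", "i6")
        },
        "rules": dataclasses.asdict(spec.rules),
        "outcome": {
            "base_mean_by_level": list(spec.outcome.base_mean_by_level),
            "matched_bonus": spec.outcome.matched_bonus,
            "mismatched_penalty": spec.outcome.mismatched_penalty,
            "a1_bonus": spec.outcome.a1_bonus,
            "a5_bonus": spec.outcome.a5_bonus,
            "sigma_by_level": list(spec.outcome.sigma_by_level),
            "nondesignated_penalty": spec.outcome.nondesignated_penalty,
        },
        "death": {
            "stage1_by_level": list(spec.death.stage1_by_level),
            "stage2_by_level": list(spec.death.stage2_by_level),
        },
        "missingness": {k: float(v) for k, v in spec.missingness.items()},
        "score_schema": spec.score_schema.to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_cohort_spec(path: str | Path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    spec = CohortSpec(
        n_patients=int(doc["n_patients"]),
        marginals=StateMarginals(
            **{
                name: {int(k): float(v) for k, v in doc["marginals"][name].items()}
                for name in ("i1", "i2", "i3", "i4", "i5", "i6")
            }
        ),
        rules=AssignmentRules(**doc.get("rules", {})),
        outcome=OutcomeModel(
            base_mean_by_level=tuple(doc["outcome"]["base_mean_by_level"]),
            matched_bonus=float(doc["outcome"]["matched_bonus"]),
            mismatched_penalty=float(doc["outcome"]["mismatched_penalty"]),
            a1_bonus=float(doc["outcome"]["a1_bonus"]),
            a5_bonus=float(doc["outcome"]["a5_bonus"]),
            sigma_by_level=tuple(doc["outcome"]["sigma_by_level"]),
            nondesignated_penalty=float(doc["outcome"].get("nondesignated_penalty", 0.0)),
        )
        if "outcome" in doc
        else OutcomeModel(),
        death=DeathModel(
            stage1_by_level=tuple(doc["death"]["stage1_by_level"]),
            stage2_by_level=tuple(doc["death"]["stage2_by_level"]),
        )
        if "death" in doc
        else DeathModel(),
        missingness={k: float(v) for k, v in doc.get("missingness", {}).items()},
        score_schema=ScoreSchema.from_dict(doc["score_schema"])
        if "score_schema" in doc
        else default_score_schema(),
        seed=int(doc.get("seed", 0)),
    )
    spec.validate()
    return spec
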