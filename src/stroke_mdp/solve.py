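"""Backward induction, policy evaluation and a brute-force oracle.

The optimality criterion is the finite-horizon expected total reward

    J(pi, i) = E_i^pi [ sum_{t=1}^{T} u_t(i_t, f_t(i_t)) + u_terminal(i_{T+1}) ],

maximized over Markov policies ``pi = (f_1, ..., f_T)`` with ``f_t(i)``
ranging over the observed admissible set ``A_t(i)``.  Backward induction
computes

    J_t(i) = max_{a in A_t(i)} [ u_t(i,a) + sum_j p_t(j|i,a) J_{t+1}(j) ]

from ``J_{T+1} = `` terminal reward (zero by default) down to stage 1; the
argmax per state is the optimal decision rule.  Ties are broken by the
lexicographically smallest action code, so the solution is deterministic.

A next state without support at the following stage contributes its
terminal reward as continuation value (dropping its mass would break row
normalization); each such fallback is logged.

:func:`brute_force_optimal` enumerates every admissible policy and is the
independent oracle the solver is tested against; :func:`random_model`
builds small random instances for such comparisons.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import EvaluationError, OracleError, SolverError, ValidationError
from .estimation import FittedMDP, RewardModel, TransitionModel
from .schemas import ActionSchema, StateSchema

logger = logging.getLogger(__name__)

__all__ = [
    "Policy",
    "ValueFunction",
    "backward_induction",
    "evaluate_policy",
    "brute_force_optimal",
    "policy_space_size",
    "support_restricted_policy",
    "random_model",
]


@dataclass
class Policy:
    """Stage-indexed decision rules ``f_t: state code -> action code``."""

    rules: dict[int, dict[str, str]]
    provenance: str = "user-supplied"

    def action(self, stage: int, state: str) -> str:
        try:
            return self.rules[stage][state]
        except KeyError:
            raise EvaluationError(f"policy has no rule for stage {stage}, state {state}")

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "rules": {str(t): dict(sorted(r.items())) for t, r in sorted(self.rules.items())},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Policy":
        return cls(
            rules={int(t): dict(r) for t, r in doc["rules"].items()},
            provenance=doc.get("provenance", "user-supplied"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Policy":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ValueFunction:
    """Stage-indexed expected total rewards ``J_t(i)`` in score units.

    Stage ``horizon + 1`` holds the terminal rewards.
    """

    values: dict[int, dict[str, float]]

    def value(self, stage: int, state: str) -> float:
        return self.values[stage][state]

    def to_dict(self) -> dict:
        return {str(t): dict(sorted(v.items())) for t, v in sorted(self.values.items())}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ValueFunction":
        return cls(values={int(t): {k: float(x) for k, x in v.items()} for t, v in doc.items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ValueFunction":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _terminal_map(
    model: FittedMDP, terminal: Mapping[str, float] | None
) -> Callable[[str], float]:
    if terminal is None:
        return model.rewards.terminal_reward
    return lambda s: terminal.get(s, 0.0)


def backward_induction(
    model: FittedMDP,
    terminal: Mapping[str, float] | None = None,
) -> tuple[Policy, ValueFunction]:
    """Solve the fitted MDP for the optimal policy and value function.

    ``terminal`` overrides the model's terminal rewards (default all
    zero); states absent from it fall back to 0.
    """
    term = _terminal_map(model, terminal)
    T = model.horizon
    values: dict[int, dict[str, float]] = {
        T + 1: {s: term(s) for s in sorted(model.states())}
    }
    rules: dict[int, dict[str, str]] = {}
    n_fallbacks = 0
    for t in range(T, 0, -1):
        values[t] = {}
        rules[t] = {}
        admissible = model.admissible(t)
        for i in sorted(model.stage_states(t)):
            actions = admissible.get(i, [])
            if not actions:
                raise SolverError(f"state {i} has support at stage {t} but no actions")
            best_a: str | None = None
            best_q = -math.inf
            for a in actions:  # sorted: first maximizer = lexicographic tie-break
                q = model.expected_reward(t, i, a)
                for j, p in model.transitions.row(t, i, a).items():
                    if j in values[t + 1]:
                        q += p * values[t + 1][j]
                    else:
                        n_fallbacks += 1
                        logger.debug(
                            "stage %d: next state %s lacks stage-%d support; "
                            "using terminal reward", t, j, t + 1
                        )
                        q += p * term(j)
                if q > best_q:
                    best_q = q
                    best_a = a
            values[t][i] = best_q
            rules[t][i] = best_a  # type: ignore[assignment]
    if n_fallbacks:
        logger.info("continuation fell back to terminal reward %d time(s)", n_fallbacks)
    return Policy(rules=rules, provenance="solved"), ValueFunction(values=values)


def _policy_values(
    model: FittedMDP,
    rules: Mapping[int, Mapping[str, str]],
    term: Callable[[str], float],
    validate: bool = True,
) -> dict[int, dict[str, float]]:
    """Expected total reward from every (stage, state) under fixed rules."""
    T = model.horizon
    values: dict[int, dict[str, float]] = {T + 1: {s: term(s) for s in model.states()}}
    for t in range(T, 0, -1):
        values[t] = {}
        admissible = model.admissible(t)
        for i in model.stage_states(t):
            a = rules.get(t, {}).get(i)
            if a is None:
                raise EvaluationError(f"policy undefined at stage {t}, state {i}")
            if validate and a not in admissible.get(i, ()):
                raise EvaluationError(
                    f"policy action {a} not admissible at stage {t}, state {i}"
                )
            u = model.expected_reward(t, i, a)
            for j, p in model.transitions.row(t, i, a).items():
                u += p * values[t + 1].get(j, term(j))
            values[t][i] = u
    return values


def evaluate_policy(
    model: FittedMDP,
    policy: Policy,
    initial_state: str | None = None,
    terminal: Mapping[str, float] | None = None,
):
    """Expected total reward of ``policy`` from an initial state.

    With ``initial_state=None``, returns the full mapping of stage-1 states
    to values.  Raises :class:`EvaluationError` if the initial state has no
    stage-1 support or the policy is not admissible.
    """
    term = _terminal_map(model, terminal)
    values = _policy_values(model, policy.rules, term)
    if initial_state is None:
        return dict(values[1])
    if initial_state not in values[1]:
        raise EvaluationError(
            f"initial state {initial_state} has no stage-1 support"
        )
    return values[1][initial_state]


def policy_space_size(model: FittedMDP) -> int:
    """``|Pi|``: the number of admissible deterministic Markov policies."""
    size = 1
    for t in model.stages():
        for _i, actions in model.admissible(t).items():
            size *= len(actions)
    return size


def brute_force_optimal(
    model: FittedMDP,
    terminal: Mapping[str, float] | None = None,
    cap: int = 1_000_000,
) -> tuple[Policy, ValueFunction]:
    """Exhaustive policy enumeration — the testing oracle.

    Evaluates every admissible policy from every state, returns the
    per-(stage, state) maximal values and the first policy (in
    lexicographic order of its action-code sequence over (stage, state)
    slots) that attains the stage-1 maximum at every state simultaneously.
    """
    size = policy_space_size(model)
    if size > cap:
        raise OracleError(
            f"policy space has {size} policies (> cap {cap}); use a smaller instance"
        )
    term = _terminal_map(model, terminal)
    T = model.horizon
    slots: list[tuple[int, str]] = []
    options: list[list[str]] = []
    for t in model.stages():
        admissible = model.admissible(t)
        for i in sorted(model.stage_states(t)):
            if not admissible.get(i):
                raise SolverError(f"state {i} has support at stage {t} but no actions")
            slots.append((t, i))
            options.append(sorted(admissible[i]))

    def rules_for(assignment: Sequence[str]) -> dict[int, dict[str, str]]:
        rules: dict[int, dict[str, str]] = {t: {} for t in model.stages()}
        for (t, i), a in zip(slots, assignment):
            rules[t][i] = a
        return rules

    # pass 1: per-(stage, state) maxima over all policies
    best: dict[int, dict[str, float]] = {t: {} for t in range(1, T + 2)}
    for assignment in itertools.product(*options):
        values = _policy_values(model, rules_for(assignment), term, validate=False)
        for t, row in values.items():
            for i, v in row.items():
                if v > best[t].get(i, -math.inf):
                    best[t][i] = v

    # pass 2: first policy attaining every stage-1 maximum (lexicographic
    # enumeration order makes it the lexicographically smallest such policy)
    tol = 1e-12
    for assignment in itertools.product(*options):
        values = _policy_values(model, rules_for(assignment), term, validate=False)
        if all(values[1][i] >= best[1][i] - tol for i in best[1]):
            policy = Policy(rules=rules_for(assignment), provenance="enumerated")
            return policy, ValueFunction(values=best)
    raise AssertionError("unreachable: some policy attains the per-state maxima")


def support_restricted_policy(
    model: FittedMDP,
    values: ValueFunction,
    min_support: int,
) -> Policy:
    """Greedy policy over actions with at least ``min_support`` episodes.

    Thinly observed treatment combinations have noisy value estimates; this
    re-derives the stage-wise argmax (using the solved continuation values)
    over actions whose (state, action) episode count reaches
    ``min_support``.  States with no sufficiently observed action are
    omitted.  Counts-backed models only.
    """
    if not model.transitions.counts:
        raise ValidationError("support-restricted policy needs a counts-backed model")
    term = model.rewards.terminal_reward
    rules: dict[int, dict[str, str]] = {}
    for t in model.stages():
        rules[t] = {}
        support = model.pair_support(t)
        for i in sorted(model.stage_states(t)):
            best_a, best_q = None, -math.inf
            for a in model.admissible(t).get(i, []):
                if support[(i, a)] < min_support:
                    continue
                q = model.expected_reward(t, i, a)
                cont = values.values.get(t + 1, {})
                for j, p in model.transitions.row(t, i, a).items():
                    q += p * cont.get(j, term(j))
                if q > best_q:
                    best_q, best_a = q, a
            if best_a is not None:
                rules[t][i] = best_a
    return Policy(rules=rules, provenance="support-restricted")


def random_model(
    seed: int | np.random.Generator,
    max_states: int = 5,
    max_actions: int = 4,
    horizon: int = 2,
    max_policies: int = 20_000,
) -> FittedMDP:
    """A small random MDP instance for oracle comparisons.

    States and actions are single-digit codes; transition rows are
    Dirichlet draws over a random support, per-transition mean rewards are
    uniform on [-5, 5], and expected rewards are derived consistently.
    Instances whose policy space would exceed ``max_policies`` are
    resampled so exhaustive enumeration stays cheap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _attempt in range(200):
        n_states = int(rng.integers(2, max_states + 1))
        n_actions = int(rng.integers(2, max_actions + 1))
        states = [str(k) for k in range(n_states)]
        actions = [str(k) for k in range(n_actions)]
        probs: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
        mean: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
        expected: dict[int, dict[tuple[str, str], float]] = {}
        log_policies = 0.0
        for t in range(1, horizon + 1):
            probs[t], mean[t], expected[t] = {}, {}, {}
            for i in states:
                k = int(rng.integers(1, n_actions + 1))
                admissible = sorted(rng.choice(actions, size=k, replace=False))
                log_policies += math.log(k)
                for a in admissible:
                    n_next = int(rng.integers(1, n_states + 1))
                    nexts = sorted(rng.choice(states, size=n_next, replace=False))
                    row = rng.dirichlet(np.ones(n_next))
                    prow = {j: float(p) for j, p in zip(nexts, row)}
                    mrow = {j: float(rng.uniform(-5, 5)) for j in nexts}
                    probs[t][(i, a)] = prow
                    mean[t][(i, a)] = mrow
                    expected[t][(i, a)] = sum(prow[j] * mrow[j] for j in nexts)
        if log_policies > math.log(max_policies):
            continue
        return FittedMDP(
            state_schema=StateSchema(alphabets=(frozenset(range(n_states)),)),
            action_schema=ActionSchema(alphabets=(frozenset(range(n_actions)),)),
            transitions=TransitionModel(probs=probs),
            rewards=RewardModel(
                mean=mean, expected=expected, terminal={s: 0.0 for s in states}
            ),
            horizon=horizon,
        )
    raise OracleError("could not sample an instance within the policy-space cap")
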