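"""Count-based estimation of the two-stage treatment MDP.

The model is the tuple ``{S, A_t(i), p_t(j|i,a), u_t(i,a)}``:

* states ``i`` are the digit-coded patient conditions,
* the admissible action set ``A_t(i)`` of a state at stage ``t`` is exactly
  the set of treatment combinations observed for it at that stage,
* ``p_t(j|i,a) = #(j,i,a) / sum_j' #(j',i,a)`` is the empirical transition
  frequency,
* ``u_t(j,i,a)`` is the mean observed stage reward over episodes moving
  ``i -> j`` under ``a``, and ``u_t(i,a) = sum_j p_t(j|i,a) u_t(j,i,a)`` —
  which equals the pooled mean reward of all ``(t,i,a)`` episodes.

No smoothing or shrinkage is applied: a probability is positive only where
a transition was observed.  Before fitting, states are support-filtered the
way the source analysis was: a state is retained only if at least
``min_count`` distinct records start (stage 1) in it, and dropping a record
removes both of its episodes.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cohort import Episode, STAGES
from .errors import ValidationError
from .schemas import (
    ActionSchema,
    StateSchema,
    default_action_schema,
    default_state_schema,
)

__all__ = [
    "TransitionModel",
    "RewardModel",
    "FittedMDP",
    "FilterReport",
    "filter_low_support_states",
    "admissible_actions",
    "estimate_transitions",
    "estimate_rewards",
    "fit_mdp",
]


@dataclass
class TransitionModel:
    """Per-stage transition table.

    ``probs[t][(i, a)][j]`` is ``p_t(j|i,a)``; ``counts`` holds the raw
    transfer counts when the model was fitted from episodes (a ground-truth
    model carries probabilities only).
    """

    probs: dict[int, dict[tuple[str, str], dict[str, float]]]
    counts: dict[int, dict[tuple[str, str], dict[str, int]]] | None = None

    @classmethod
    def from_counts(
        cls, counts: Mapping[int, Mapping[tuple[str, str], Mapping[str, int]]]
    ) -> "TransitionModel":
        probs: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
        frozen: dict[int, dict[tuple[str, str], dict[str, int]]] = {}
        for t, table in counts.items():
            probs[t] = {}
            frozen[t] = {}
            for pair, row in table.items():
                total = sum(row.values())
                probs[t][pair] = {j: c / total for j, c in row.items()}
                frozen[t][pair] = dict(row)
        return cls(probs=probs, counts=frozen)

    def stages(self) -> tuple[int, ...]:
        return tuple(sorted(self.probs))

    def pairs(self, stage: int) -> Iterable[tuple[str, str]]:
        return self.probs.get(stage, {}).keys()

    def row(self, stage: int, state: str, action: str) -> dict[str, float]:
        return self.probs.get(stage, {}).get((state, action), {})


@dataclass
class RewardModel:
    """Per-transition mean rewards, expected rewards and terminal rewards."""

    mean: dict[int, dict[tuple[str, str], dict[str, float]]]
    expected: dict[int, dict[tuple[str, str], float]]
    terminal: dict[str, float] = field(default_factory=dict)

    def terminal_reward(self, state: str) -> float:
        return self.terminal.get(state, 0.0)


@dataclass
class FilterReport:
    """Outcome of the low-support state filter."""

    min_count: int
    retained: set[str]
    dropped: dict[str, int]
    n_records_before: int
    n_records_after: int
    n_episodes_before: int
    n_episodes_after: int

    def to_dict(self) -> dict:
        return {
            "min_count": self.min_count,
            "retained_states": sorted(self.retained),
            "dropped_states": dict(sorted(self.dropped.items())),
            "n_records_before": self.n_records_before,
            "n_records_after": self.n_records_after,
            "n_episodes_before": self.n_episodes_before,
            "n_episodes_after": self.n_episodes_after,
        }


@dataclass
class FittedMDP:
    """A finite-horizon MDP over digit-coded states and actions.

    ``horizon`` is the number of decision stages (2 for the admission ->
    day-3 -> discharge design); stage ``horizon + 1`` carries only the
    terminal reward (zero by default).
    """

    state_schema: StateSchema
    action_schema: ActionSchema
    transitions: TransitionModel
    rewards: RewardModel
    horizon: int = 2

    def stages(self) -> tuple[int, ...]:
        return tuple(range(1, self.horizon + 1))

    def states(self) -> set[str]:
        out: set[str] = set()
        for t in self.transitions.stages():
            for (i, _a), row in self.transitions.probs[t].items():
                out.add(i)
                out.update(row)
        return out

    def stage_states(self, stage: int) -> set[str]:
        return {i for (i, _a) in self.transitions.pairs(stage)}

    def admissible(self, stage: int) -> dict[str, list[str]]:
        """Observed action sets ``A_t(i)``, actions sorted by code."""
        sets: dict[str, set[str]] = defaultdict(set)
        for (i, a) in self.transitions.pairs(stage):
            sets[i].add(a)
        return {i: sorted(acts) for i, acts in sets.items()}

    def state_support(self, stage: int) -> Counter:
        """Episode counts per state at a stage (counts-backed models only)."""
        support: Counter = Counter()
        if self.transitions.counts:
            for (i, _a), row in self.transitions.counts.get(stage, {}).items():
                support[i] += sum(row.values())
        return support

    def pair_support(self, stage: int) -> Counter:
        support: Counter = Counter()
        if self.transitions.counts:
            for pair, row in self.transitions.counts.get(stage, {}).items():
                support[pair] += sum(row.values())
        return support

    def expected_reward(self, stage: int, state: str, action: str) -> float:
        return self.rewards.expected[stage][(state, action)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        stages_doc: dict[str, list[dict]] = {}
        for t in self.transitions.stages():
            rows: list[dict] = []
            for (i, a) in sorted(self.transitions.probs[t]):
                prow = self.transitions.probs[t][(i, a)]
                crow = (
                    self.transitions.counts[t][(i, a)]
                    if self.transitions.counts
                    else None
                )
                mrow = self.rewards.mean[t][(i, a)]
                for j in sorted(prow):
                    rows.append(
                        {
                            "state": i,
                            "action": a,
                            "next_state": j,
                            "count": None if crow is None else crow[j],
                            "prob": prow[j],
                            "mean_reward": mrow[j],
                        }
                    )
            stages_doc[str(t)] = rows
        return {
            "state_schema": self.state_schema.to_dict(),
            "action_schema": self.action_schema.to_dict(),
            "horizon": self.horizon,
            "stages": stages_doc,
            "terminal_rewards": dict(sorted(self.rewards.terminal.items())),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FittedMDP":
        probs: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
        counts: dict[int, dict[tuple[str, str], dict[str, int]]] = {}
        mean: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
        has_counts = True
        for t_str, rows in doc["stages"].items():
            t = int(t_str)
            probs[t] = defaultdict(dict)
            counts[t] = defaultdict(dict)
            mean[t] = defaultdict(dict)
            for row in rows:
                pair = (row["state"], row["action"])
                probs[t][pair][row["next_state"]] = float(row["prob"])
                mean[t][pair][row["next_state"]] = float(row["mean_reward"])
                if row.get("count") is None:
                    has_counts = False
                else:
                    counts[t][pair][row["next_state"]] = int(row["count"])
            probs[t] = dict(probs[t])
            counts[t] = dict(counts[t])
            mean[t] = dict(mean[t])
        transitions = TransitionModel(
            probs=probs, counts=counts if has_counts else None
        )
        expected = {
            t: {
                pair: sum(
                    probs[t][pair][j] * mean[t][pair][j] for j in probs[t][pair]
                )
                for pair in probs[t]
            }
            for t in probs
        }
        rewards = RewardModel(
            mean=mean,
            expected=expected,
            terminal={k: float(v) for k, v in doc.get("terminal_rewards", {}).items()},
        )
        return cls(
            state_schema=StateSchema.from_dict(doc["state_schema"]),
            action_schema=ActionSchema.from_dict(doc["action_schema"]),
            transitions=transitions,
            rewards=rewards,
            horizon=int(doc["horizon"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FittedMDP":
        return cls.from_dict(json.loads(Path(path).read_text()))


def filter_low_support_states(
    episodes: Sequence[Episode], min_count: int
) -> tuple[set[str], list[Episode], FilterReport]:
    """Drop records whose admission state is too rare.

    A state is retained iff at least ``min_count`` distinct records have it
    as their stage-1 state ("more than 10 (including 10)" in the source
    analysis, hence the default elsewhere of 10 with ``>=`` semantics).
    Dropping a record removes both of its episodes.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    stage1_state: dict[str, str] = {}
    for e in episodes:
        if e.stage == 1:
            stage1_state[e.record_id] = e.state
    state_records = Counter(stage1_state.values())
    retained = {s for s, n in state_records.items() if n >= min_count}
    dropped = {s: n for s, n in state_records.items() if n < min_count}
    kept = [
        e
        for e in episodes
        if stage1_state.get(e.record_id) in retained
    ]
    report = FilterReport(
        min_count=min_count,
        retained=retained,
        dropped=dropped,
        n_records_before=len(stage1_state),
        n_records_after=sum(state_records[s] for s in retained),
        n_episodes_before=len(episodes),
        n_episodes_after=len(kept),
    )
    return retained, kept, report


def admissible_actions(
    episodes: Sequence[Episode], stage: int
) -> dict[str, set[str]]:
    """``A_t(i)``: action codes observed for each state at ``stage``."""
    if stage not in STAGES:
        raise ValidationError(f"stage {stage} not in {STAGES}")
    sets: dict[str, set[str]] = defaultdict(set)
    for e in episodes:
        if e.stage == stage:
            sets[e.state].add(e.action)
    return dict(sets)


def estimate_transitions(episodes: Sequence[Episode]) -> TransitionModel:
    """Empirical transition frequencies per stage and (state, action)."""
    counts: dict[int, dict[tuple[str, str], Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for e in episodes:
        counts[e.stage][(e.state, e.action)][e.next_state] += 1
    return TransitionModel.from_counts(
        {t: {pair: dict(row) for pair, row in table.items()} for t, table in counts.items()}
    )


def estimate_rewards(
    episodes: Sequence[Episode], transitions: TransitionModel
) -> RewardModel:
    """Mean observed rewards per transition; expected rewards per action.

    ``u_t(j,i,a)`` is the arithmetic mean of episode rewards with that
    ``(t,i,a,j)``; ``u_t(i,a)`` follows as the probability-weighted sum,
    which coincides with the pooled mean of all ``(t,i,a)`` rewards.
    Terminal rewards default to zero for every state.
    """
    sums: dict[int, dict[tuple[str, str], dict[str, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float))
    )
    ns: dict[int, dict[tuple[str, str], dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int))
    )
    for e in episodes:
        sums[e.stage][(e.state, e.action)][e.next_state] += e.reward
        ns[e.stage][(e.state, e.action)][e.next_state] += 1
    mean: dict[int, dict[tuple[str, str], dict[str, float]]] = {}
    expected: dict[int, dict[tuple[str, str], float]] = {}
    for t in transitions.stages():
        mean[t] = {}
        expected[t] = {}
        for pair, prow in transitions.probs[t].items():
            mrow = {
                j: sums[t][pair][j] / ns[t][pair][j] for j in prow
            }
            mean[t][pair] = mrow
            expected[t][pair] = sum(prow[j] * mrow[j] for j in prow)
    terminal = {s: 0.0 for t in transitions.stages() for pair in transitions.probs[t] for s in transitions.probs[t][pair]}
    terminal.update({pair[0]: 0.0 for t in transitions.stages() for pair in transitions.probs[t]})
    return RewardModel(mean=mean, expected=expected, terminal=terminal)


def fit_mdp(
    episodes: Sequence[Episode],
    state_schema: StateSchema | None = None,
    action_schema: ActionSchema | None = None,
    min_count: int = 10,
    horizon: int = 2,
) -> tuple[FittedMDP, FilterReport]:
    """Support-filter episodes and estimate the full MDP from them."""
    state_schema = state_schema or default_state_schema()
    action_schema = action_schema or default_action_schema()
    _retained, kept, report = filter_low_support_states(episodes, min_count)
    transitions = estimate_transitions(kept)
    rewards = estimate_rewards(kept, transitions)
    model = FittedMDP(
        state_schema=state_schema,
        action_schema=action_schema,
        transitions=transitions,
        rewards=rewards,
        horizon=horizon,
    )
    return model, report
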