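import hypothesis
import pytest

from stroke_mdp import (
    PatientRecord,
    default_action_schema,
    default_score_schema,
    default_state_schema,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def score_schema():
    return default_score_schema()


@pytest.fixture(scope="session")
def state_schema():
    return default_state_schema()


@pytest.fixture(scope="session")
def action_schema():
    return default_action_schema()


def greedy_items(score: int, schema) -> dict:
    """Deterministic item allocation summing to ``score``."""
    out = {}
    remaining = score
    for name, cap in schema.item_max.items():
        take = min(cap, remaining)
        out[name] = take
        remaining -= take
    assert remaining == 0, f"score {score} exceeds instrument range"
    return out


def make_record(
    record_id: str,
    scores: tuple[int, int, int],
    schema,
    actions=((1, 0, 0, 0, 1), (1, 0, 0, 0, 1)),
    death=(False, False, False),
    chars=(2, 0, 0, 1, 1),
    admission_date: str | None = None,
) -> PatientRecord:
    """A complete three-timepoint record with the given total scores."""
    return PatientRecord(
        record_id=record_id,
        admission_date=admission_date,
        characteristics={f"i{k+1}": chars[k] for k in range(5)},
        item_scores={
            t: greedy_items(scores[t - 1], schema) for t in (1, 2, 3)
        },
        death={t: death[t - 1] for t in (1, 2, 3)},
        actions={1: tuple(actions[0]), 2: tuple(actions[1])},
    )
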