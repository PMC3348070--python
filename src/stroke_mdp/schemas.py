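"""Coding schemas for patient states, treatment actions and impairment scores.

A patient *state* is a 6-component vector ``(i1..i6)``:

====  =========================================  =================
comp  meaning                                    default alphabet
====  =========================================  =================
i1    age band (1: <=45, 2: 46-65, 3: >=66)      {1, 2, 3}
i2    any disease history                        {0, 1}
i3    any complication during the stay           {0, 1}
i4    TCM diagnosis (1: channels/collaterals,    {1, 2}
      2: zang-fu organs)
i5    TCM pattern (1: Yang, 2: Yin,              {1, 2, 3, 4}
      3: composite, 4: other)
i6    neurological-function level                {1, 2, 3, 4, 5}
====  =========================================  =================

A treatment *action* is a 5-flag combination ``(a1..a5)``: antiplatelet /
anticoagulant agents, Yi Qi Wen Yang, Qing Re Xi Feng, bowel-relaxing
treatment, herbal medicine; each flag is 0/1.

States and actions are serialised as concatenated digit strings
(``"200111"``, ``"01011"``), which is also how they key every table in this
package.

The neurological impairment score is an additive instrument over a small
set of items (consciousness, limb power, ...) with a fixed total maximum of
29; death is recorded as the maximal score.  The shipped default item
weights are a stand-in instrument with the right structure (nine
NIHSS-style items whose maxima sum to 29), not any hospital's exact scale;
pass a custom :class:`ScoreSchema` to use a real one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "ScoreSchema",
    "StateSchema",
    "ActionSchema",
    "default_score_schema",
    "default_state_schema",
    "default_action_schema",
    "score_to_level",
    "level_band",
    "level_band_midpoint",
    "LEVEL_BANDS",
]

#: Score bands defining the neurological-function level (i6).
LEVEL_BANDS: tuple[tuple[int, int], ...] = ((0, 2), (3, 5), (6, 12), (13, 19), (20, 29))


def score_to_level(score: int) -> int:
    """Map a 0-29 impairment score to its severity level 1-5.

    Bands: 0-2 -> 1, 3-5 -> 2, 6-12 -> 3, 13-19 -> 4, 20-29 -> 5.
    """
    if not (0 <= score <= 29):
        raise ValidationError(f"score {score!r} outside [0, 29]")
    for level, (lo, hi) in enumerate(LEVEL_BANDS, start=1):
        if lo <= score <= hi:
            return level
    raise AssertionError("unreachable: bands cover [0, 29]")


def level_band(level: int) -> tuple[int, int]:
    """Inclusive (low, high) score range of a severity level."""
    if not (1 <= level <= 5):
        raise ValidationError(f"level {level!r} outside 1..5")
    return LEVEL_BANDS[level - 1]


def level_band_midpoint(level: int) -> float:
    lo, hi = level_band(level)
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class ScoreSchema:
    """Additive impairment-score instrument.

    Parameters
    ----------
    item_max
        Ordered mapping item name -> maximal integer contribution.
    total_max
        Total score ceiling; must equal the sum of the item maxima.
        A dead patient scores ``total_max`` regardless of items.
    """

    item_max: Mapping[str, int]
    total_max: int = 29

    def __post_init__(self):
        if any(m < 0 for m in self.item_max.values()):
            raise ValidationError("item maxima must be >= 0")
        total = sum(self.item_max.values())
        if total != self.total_max:
            raise ValidationError(
                f"item maxima sum to {total}, expected total_max={self.total_max}"
            )

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(self.item_max)

    @property
    def death_score(self) -> int:
        return self.total_max

    def to_dict(self) -> dict:
        return {"item_max": dict(self.item_max), "total_max": self.total_max}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreSchema":
        return cls(item_max=dict(d["item_max"]), total_max=int(d["total_max"]))


#: Stand-in 29-point instrument (see module docstring).
DEFAULT_SCORE_ITEMS: dict[str, int] = {
    "consciousness": 5,
    "visual_field": 2,
    "facial_paralysis": 2,
    "upper_limb": 5,
    "lower_limb": 5,
    "ataxia": 2,
    "sensory": 2,
    "aphasia": 3,
    "dysarthria": 3,
}


def default_score_schema() -> ScoreSchema:
    return ScoreSchema(item_max=dict(DEFAULT_SCORE_ITEMS))


@dataclass(frozen=True)
class _CodeSchema:
    """Shared machinery for digit-string coding of component vectors."""

    alphabets: tuple[frozenset[int], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        for k, alpha in enumerate(self.alphabets):
            if not alpha or not all(0 <= d <= 9 for d in alpha):
                raise ValidationError(
                    f"component {k + 1}: alphabet must be a non-empty subset of 0..9"
                )

    def __len__(self) -> int:
        return len(self.alphabets)

    def validate(self, components: Sequence[int]) -> tuple[int, ...]:
        comps = tuple(int(c) for c in components)
        if len(comps) != len(self.alphabets):
            raise ValidationError(
                f"expected {len(self.alphabets)} components, got {len(comps)}"
            )
        for k, (c, alpha) in enumerate(zip(comps, self.alphabets)):
            if c not in alpha:
                raise ValidationError(
                    f"component {k + 1} value {c} not in alphabet {sorted(alpha)}"
                )
        return comps

    def encode(self, components: Sequence[int]) -> str:
        """Concatenate validated components into a digit-string code."""
        return "".join(str(c) for c in self.validate(components))

    def decode(self, code: str) -> tuple[int, ...]:
        """Inverse of :meth:`encode`."""
        if len(code) != len(self.alphabets) or not code.isdigit():
            raise ValidationError(
                f"code {code!r}: expected {len(self.alphabets)} digits"
            )
        return self.validate(tuple(int(ch) for ch in code))

    def to_dict(self) -> dict:
        return {
            "alphabets": [sorted(a) for a in self.alphabets],
            "labels": list(self.labels),
        }


@dataclass(frozen=True)
class StateSchema(_CodeSchema):
    """Digit alphabets and labels of the 6-component patient state."""

    @classmethod
    def from_dict(cls, d: Mapping) -> "StateSchema":
        return cls(
            alphabets=tuple(frozenset(a) for a in d["alphabets"]),
            labels=tuple(d.get("labels", ())),
        )


@dataclass(frozen=True)
class ActionSchema(_CodeSchema):
    """Digit alphabets and labels of the 5-flag treatment combination."""

    @classmethod
    def from_dict(cls, d: Mapping) -> "ActionSchema":
        return cls(
            alphabets=tuple(frozenset(a) for a in d["alphabets"]),
            labels=tuple(d.get("labels", ())),
        )


_STATE_LABELS = (
    "age band",
    "disease history",
    "complication",
    "TCM diagnosis",
    "TCM pattern",
    "neurological-function level",
)

_ACTION_LABELS = (
    "antiplatelet/anticoagulant",
    "Yi Qi Wen Yang",
    "Qing Re Xi Feng",
    "relax bowels",
    "herbal medicine",
)


def default_state_schema() -> StateSchema:
    return StateSchema(
        alphabets=(
            frozenset({1, 2, 3}),
            frozenset({0, 1}),
            frozenset({0, 1}),
            frozenset({1, 2}),
            frozenset({1, 2, 3, 4}),
            frozenset({1, 2, 3, 4, 5}),
        ),
        labels=_STATE_LABELS,
    )


def default_action_schema() -> ActionSchema:
    return ActionSchema(
        alphabets=tuple(frozenset({0, 1}) for _ in range(5)),
        labels=_ACTION_LABELS,
    )
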