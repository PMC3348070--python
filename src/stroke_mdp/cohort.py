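"""Cohort reading, impairment scoring, imputation and episode extraction.

A cohort is a CSV table, one row per hospitalization record, holding the
five once-assessed patient characteristics (``i1..i5``), per-timepoint item
scores of the neurological impairment instrument and death flags for the
three assessment timepoints (admission *t1*, day-3 *t2*, discharge *t3*),
and the five binary treatment flags for each of the two treatment stages
(*stage 1* = t1->t2, *stage 2* = t2->t3).

Each usable record yields exactly two state-action-reward episodes.  The
state at a timepoint is ``(i1..i5, level)`` where ``level`` bands the total
impairment score; the reward of a stage is ``score_before - score_after``
(positive = improvement).  A dead patient scores the instrument maximum, so
death enters the model as maximal severity and stage rewards still
telescope to ``score(t1) - score(t3)``.

Missing values are imputed column-wise by the median of nearby points:
records are sorted by admission date then record id, and each gap takes the
median of up to ``span`` non-missing neighbours on each side of it in that
ordering.  Imputed item values are rounded half-to-even back to integers.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    ImputationError,
    InputError,
    RecordRejected,
    ValidationError,
)
from .schemas import (
    ActionSchema,
    ScoreSchema,
    StateSchema,
    default_action_schema,
    default_state_schema,
    score_to_level,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "Episode",
    "TIMEPOINTS",
    "STAGES",
    "MISSING_MARKERS",
    "default_column_map",
    "read_cohort",
    "write_cohort",
    "compute_neuro_score",
    "impute_missing",
    "impute_cohort",
    "extract_episodes",
    "build_episodes",
    "write_episodes",
    "read_episodes",
]

TIMEPOINTS = (1, 2, 3)
STAGES = (1, 2)

#: Cell contents treated as missing on input.
MISSING_MARKERS = ("", "NA")

_CHARACTERISTICS = ("i1", "i2", "i3", "i4", "i5")


@dataclass
class PatientRecord:
    """One hospitalization record.

    ``characteristics`` holds ``i1..i5`` (assessed once; ``None`` =
    missing).  ``item_scores[t]`` maps item name -> integer or ``None`` for
    each timepoint; ``death[t]`` flags death at or before timepoint ``t``;
    ``actions[s]`` is the 5-tuple of treatment flags of stage ``s`` (each
    0/1 or ``None``).
    """

    record_id: str
    characteristics: dict[str, int | None]
    item_scores: dict[int, dict[str, int | None]]
    death: dict[int, bool]
    actions: dict[int, tuple[int | None, ...]]
    admission_date: str | None = None

    def validate(self) -> None:
        if sorted(self.item_scores) != list(TIMEPOINTS) or sorted(self.death) != list(
            TIMEPOINTS
        ):
            raise ValidationError(
                f"record {self.record_id}: expected timepoints {TIMEPOINTS}"
            )
        if sorted(self.actions) != list(STAGES):
            raise ValidationError(f"record {self.record_id}: expected stages {STAGES}")
        # death is absorbing
        for t_prev, t_next in zip(TIMEPOINTS, TIMEPOINTS[1:]):
            if self.death[t_prev] and not self.death[t_next]:
                raise ValidationError(
                    f"record {self.record_id}: death at t{t_prev} not absorbing"
                )


@dataclass(frozen=True)
class Episode:
    """One state-action-reward-next-state tuple at stage 1 or 2."""

    record_id: str
    stage: int
    state: str
    action: str
    next_state: str
    reward: int

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"stage {self.stage} not in {STAGES}")
        if not (-29 <= self.reward <= 29):
            raise ValidationError(f"reward {self.reward} outside [-29, 29]")


def default_column_map(schema: ScoreSchema) -> dict[str, str]:
    """Identity column map for the package's own CSV dialect.

    Logical keys: ``record_id``, ``admission_date``, ``i1..i5``,
    ``death_t{1,2,3}``, ``{item}_t{1,2,3}`` and ``a{1..5}_s{1,2}``.
    """
    cols = ["record_id", "admission_date", *_CHARACTERISTICS]
    for t in TIMEPOINTS:
        cols.append(f"death_t{t}")
        cols.extend(f"{item}_t{t}" for item in schema.item_names)
    for s in STAGES:
        cols.extend(f"a{k}_s{s}" for k in range(1, 6))
    return {c: c for c in cols}


def compute_neuro_score(
    items: Mapping[str, int], death: bool, schema: ScoreSchema
) -> int:
    """Total neurological impairment score at one timepoint.

    Death forces the instrument maximum (29 under the default schema)
    regardless of item values; otherwise the score is the sum of the items,
    each validated against its maximum.
    """
    if death:
        return schema.death_score
    total = 0
    for name in schema.item_names:
        if name not in items or items[name] is None:
            raise ValidationError(f"item {name!r} missing; impute before scoring")
        value = items[name]
        if value != int(value):
            raise ValidationError(f"item {name!r} value {value!r} is not an integer")
        value = int(value)
        if not (0 <= value <= schema.item_max[name]):
            raise ValidationError(
                f"item {name!r} value {value} outside [0, {schema.item_max[name]}]"
            )
        total += value
    if total > schema.total_max:
        raise ValidationError(
            f"total {total} exceeds schema maximum {schema.total_max}"
        )
    return total


def impute_missing(
    values: Sequence[float | None], span: int = 2
) -> list[float]:
    """Fill gaps with the median of nearby points.

    Each missing entry is replaced by the median of up to ``span``
    non-missing neighbours on each side of it (in sequence order);
    non-missing entries are returned unchanged.  Raises
    :class:`ImputationError` listing the positions of gaps that have no
    non-missing neighbour within the window.
    """
    if span < 1:
        raise ValidationError(f"span must be >= 1, got {span}")
    out: list[float] = list(values)
    unfillable: list[int] = []
    for idx, v in enumerate(values):
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            continue
        neighbours: list[float] = []
        # up to `span` non-missing values on each side
        for direction in (-1, 1):
            found = 0
            j = idx + direction
            while 0 <= j < len(values) and found < span:
                w = values[j]
                if w is not None and not (isinstance(w, float) and math.isnan(w)):
                    neighbours.append(float(w))
                    found += 1
                j += direction
        if not neighbours:
            unfillable.append(idx)
        else:
            out[idx] = median(neighbours)
    if unfillable:
        raise ImputationError(
            f"no non-missing neighbours within window for positions {unfillable}"
        )
    return out  # type: ignore[return-value]


def _sorted_for_imputation(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    return sorted(records, key=lambda r: (r.admission_date or "", r.record_id))


def impute_cohort(
    records: Sequence[PatientRecord],
    schema: ScoreSchema,
    span: int = 2,
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Column-wise nearby-median imputation over a whole cohort.

    Records are sorted by admission date then record id; every
    characteristic column (``i1..i5``) and every (item, timepoint) column is
    imputed independently with :func:`impute_missing`.  Imputed values are
    rounded half-to-even to integers.  Treatment flags are never imputed.

    Returns the records (same objects, mutated in place, in the imputation
    ordering) and a per-column count of imputed cells.
    """
    ordered = _sorted_for_imputation(records)
    imputed_counts: dict[str, int] = {}

    def _impute_column(colname, getter, setter):
        values = [getter(r) for r in ordered]
        n_missing = sum(v is None for v in values)
        if n_missing == 0:
            return
        filled = impute_missing(values, span=span)
        for r, old, new in zip(ordered, values, filled):
            if old is None:
                setter(r, round(new))  # round-half-even back to integer
        imputed_counts[colname] = n_missing

    for ch in _CHARACTERISTICS:
        _impute_column(
            ch,
            lambda r, ch=ch: r.characteristics.get(ch),
            lambda r, v, ch=ch: r.characteristics.__setitem__(ch, v),
        )
    for t in TIMEPOINTS:
        for item in schema.item_names:
            _impute_column(
                f"{item}_t{t}",
                lambda r, t=t, item=item: r.item_scores[t].get(item),
                lambda r, v, t=t, item=item: r.item_scores[t].__setitem__(item, v),
            )
    return ordered, imputed_counts


def extract_episodes(
    record: PatientRecord,
    schema: ScoreSchema,
    state_schema: StateSchema | None = None,
    action_schema: ActionSchema | None = None,
) -> tuple[Episode, Episode]:
    """Segment one record into its two stage episodes.

    The stage-1 episode runs t1 -> t2 and the stage-2 episode t2 -> t3;
    each reward is the score before the stage minus the score after it.
    The state at a timepoint is ``(i1..i5, level(score))``.

    Raises :class:`RecordRejected` (with a machine-readable ``reason``) for
    records that cannot enter the model: death at admission, incomplete
    characteristics or item scores, or incomplete treatment flags.
    """
    state_schema = state_schema or default_state_schema()
    action_schema = action_schema or default_action_schema()
    record.validate()

    if record.death[1]:
        raise RecordRejected("death_at_admission", record.record_id)
    chars = [record.characteristics.get(ch) for ch in _CHARACTERISTICS]
    if any(c is None for c in chars):
        raise RecordRejected("incomplete_characteristics", record.record_id)
    for s in STAGES:
        flags = record.actions[s]
        if len(flags) != len(action_schema) or any(a is None for a in flags):
            raise RecordRejected("incomplete_actions", f"{record.record_id} stage {s}")

    scores: dict[int, int] = {}
    for t in TIMEPOINTS:
        try:
            scores[t] = compute_neuro_score(
                record.item_scores[t], record.death[t], schema
            )
        except ValidationError as exc:
            raise RecordRejected("incomplete_items", f"{record.record_id}: {exc}")

    codes = {
        t: state_schema.encode([*chars, score_to_level(scores[t])]) for t in TIMEPOINTS
    }
    episodes = tuple(
        Episode(
            record_id=record.record_id,
            stage=s,
            state=codes[s],
            action=action_schema.encode(record.actions[s]),
            next_state=codes[s + 1],
            reward=scores[s] - scores[s + 1],
        )
        for s in STAGES
    )
    return episodes  # type: ignore[return-value]


def build_episodes(
    records: Sequence[PatientRecord],
    schema: ScoreSchema,
    state_schema: StateSchema | None = None,
    action_schema: ActionSchema | None = None,
) -> tuple[list[Episode], Counter]:
    """Extract episodes from every usable record.

    Rejected records are excluded (never silently) and tallied by reason in
    the returned counter; each exclusion is logged.
    """
    episodes: list[Episode] = []
    exclusions: Counter = Counter()
    for record in records:
        try:
            episodes.extend(
                extract_episodes(record, schema, state_schema, action_schema)
            )
        except RecordRejected as exc:
            exclusions[exc.reason] += 1
            logger.info("record %s excluded: %s", record.record_id, exc)
    return episodes, exclusions


# ---------------------------------------------------------------------------
# CSV input/output


def _parse_int_cell(raw: str) -> int | None:
    """Integer from a cell; ``None`` if missing or unparseable."""
    text = raw.strip()
    if text in MISSING_MARKERS:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    if value != int(value):
        return None
    return int(value)


_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""} | set(MISSING_MARKERS)


def _parse_death_cell(raw: str, where: str) -> bool:
    # Blank death cells read as alive: deaths-only recording is the usual
    # EHR encoding, and a missing flag is not imputable.
    text = raw.strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise InputError(f"unrecognized death flag {raw!r} at {where}")


def read_cohort(
    path: str | Path,
    schema: ScoreSchema,
    column_map: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a cohort CSV into :class:`PatientRecord` objects.

    ``column_map`` maps the logical column names of
    :func:`default_column_map` to the file's actual headers; by default the
    headers are expected to match the logical names.  Blank and ``"NA"``
    cells are recorded as missing (never silently zeroed).  A parseable but
    out-of-alphabet state or action cell (e.g. an action flag of ``2``) is
    an :class:`InputError` naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    cmap = dict(default_column_map(schema))
    if column_map:
        unknown = set(column_map) - set(cmap)
        if unknown:
            raise ConfigurationError(f"unknown logical columns in map: {sorted(unknown)}")
        cmap.update(column_map)

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    optional = {"admission_date"} | {f"death_t{t}" for t in TIMEPOINTS}
    required = [c for c in cmap if c not in optional]
    missing_cols = [cmap[c] for c in required if cmap[c] not in frame.columns]
    if missing_cols:
        raise ConfigurationError(f"cohort file lacks mandatory columns: {missing_cols}")

    state_schema = default_state_schema()
    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        row_map = dict(zip(frame.columns, row))

        def cell(logical: str) -> str:
            col = cmap.get(logical, logical)
            return row_map.get(col, "")

        record_id = cell("record_id").strip()
        if not record_id:
            raise InputError(f"row {pos}: empty record_id")
        if record_id in seen_ids:
            raise InputError(f"row {pos}: duplicate record_id {record_id!r}")
        seen_ids.add(record_id)

        chars: dict[str, int | None] = {}
        for k, ch in enumerate(_CHARACTERISTICS):
            value = _parse_int_cell(cell(ch))
            if value is not None and value not in state_schema.alphabets[k]:
                raise InputError(
                    f"row {pos}, column {cmap[ch]!r}: value {value} outside "
                    f"alphabet {sorted(state_schema.alphabets[k])}"
                )
            chars[ch] = value

        item_scores: dict[int, dict[str, int | None]] = {}
        death: dict[int, bool] = {}
        for t in TIMEPOINTS:
            death[t] = _parse_death_cell(cell(f"death_t{t}"), f"row {pos}")
            per_item: dict[str, int | None] = {}
            for item in schema.item_names:
                value = _parse_int_cell(cell(f"{item}_t{t}"))
                if value is not None and not (0 <= value <= schema.item_max[item]):
                    raise InputError(
                        f"row {pos}, column {cmap[f'{item}_t{t}']!r}: value {value} "
                        f"outside [0, {schema.item_max[item]}]"
                    )
                per_item[item] = value
            item_scores[t] = per_item

        actions: dict[int, tuple[int | None, ...]] = {}
        for s in STAGES:
            flags: list[int | None] = []
            for k in range(1, 6):
                logical = f"a{k}_s{s}"
                value = _parse_int_cell(cell(logical))
                if value is not None and value not in (0, 1):
                    raise InputError(
                        f"row {pos}, column {cmap[logical]!r}: action flag {value} "
                        "not in {0, 1}"
                    )
                flags.append(value)
            actions[s] = tuple(flags)

        record = PatientRecord(
            record_id=record_id,
            admission_date=cell("admission_date").strip() or None,
            characteristics=chars,
            item_scores=item_scores,
            death=death,
            actions=actions,
        )
        record.validate()
        records.append(record)
    return records


def write_cohort(
    records: Iterable[PatientRecord],
    path: str | Path,
    schema: ScoreSchema,
) -> None:
    """Write records as CSV in the package's own dialect (missing -> blank)."""
    cols = list(default_column_map(schema))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            row: list[str] = [r.record_id, r.admission_date or ""]
            row.extend(
                "" if r.characteristics.get(ch) is None else str(r.characteristics[ch])
                for ch in _CHARACTERISTICS
            )
            for t in TIMEPOINTS:
                row.append("1" if r.death[t] else "0")
                row.extend(
                    "" if r.item_scores[t].get(item) is None else str(r.item_scores[t][item])
                    for item in schema.item_names
                )
            for s in STAGES:
                row.extend("" if a is None else str(a) for a in r.actions[s])
            writer.writerow(row)


_EPISODE_COLUMNS = ("record_id", "stage", "state_code", "action_code", "next_state_code", "reward")


def write_episodes(episodes: Iterable[Episode], path: str | Path) -> None:
    """Write the normalized episode table as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_EPISODE_COLUMNS)
        for e in episodes:
            writer.writerow([e.record_id, e.stage, e.state, e.action, e.next_state, e.reward])


def read_episodes(path: str | Path) -> list[Episode]:
    """Read an episode TSV written by :func:`write_episodes`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_EPISODE_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"episode table lacks columns: {sorted(missing)}")
    return [
        Episode(
            record_id=row.record_id,
            stage=int(row.stage),
            state=row.state_code,
            action=row.action_code,
            next_state=row.next_state_code,
            reward=int(row.reward),
        )
        for row in frame.itertuples(index=False)
    ]
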