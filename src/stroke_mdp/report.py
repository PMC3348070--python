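"""Policy tables and the end-to-end pipeline runner.

The stage tables mirror the layout of the source analysis: one row per
retained state with support at the stage, ordered by descending case count
then state code, showing the six state digits, the five digits of the
optimal treatment combination, and the reward columns to three decimals.
Two reward columns are emitted — the expected immediate reward of the
chosen action ``u_t(i, f_t(i))`` and the total value ``J_t(i)`` — because
with a zero terminal reward they coincide at the final stage but not
before, and published tables are ambiguous about which they print.

Tables are views: every number in them is recomputable from the emitted
model JSON alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cohort import (
    build_episodes,
    impute_cohort,
    read_cohort,
    write_episodes,
)
from .errors import ConfigurationError, ReportingError, ValidationError
from .estimation import FilterReport, FittedMDP, fit_mdp
from .schemas import (
    ScoreSchema,
    default_score_schema,
)
from .solve import Policy, ValueFunction, backward_induction

logger = logging.getLogger(__name__)

__all__ = [
    "PolicyTableRow",
    "RunConfig",
    "RunReport",
    "policy_table",
    "format_policy_table",
    "run_pipeline",
]


@dataclass(frozen=True)
class PolicyTableRow:
    """One line of a stage policy table."""

    n_cases: int
    state: str
    action: str
    expected_reward: float  # u_t(i, f_t(i))
    total_value: float  # J_t(i)


def policy_table(
    policy: Policy,
    values: ValueFunction,
    model: FittedMDP,
    stage: int,
) -> list[PolicyTableRow]:
    """Rows of the optimal-treatment table for one stage.

    One row per state with support at the stage, sorted by descending case
    count then state code.
    """
    if stage not in policy.rules or stage not in values.values:
        raise ReportingError(f"no solution available for stage {stage}")
    support = model.state_support(stage)
    rows = []
    for state in model.stage_states(stage):
        action = policy.rules[stage].get(state)
        if action is None:
            raise ReportingError(f"policy lacks a rule for state {state} at stage {stage}")
        rows.append(
            PolicyTableRow(
                n_cases=support[state],
                state=state,
                action=action,
                expected_reward=model.expected_reward(stage, state, action),
                total_value=values.values[stage][state],
            )
        )
    rows.sort(key=lambda r: (-r.n_cases, r.state))
    return rows


def format_policy_table(rows: Sequence[PolicyTableRow], decimals: int = 3) -> str:
    """Render rows as TSV with digit-split state/action columns.

    Reward values are rounded half-to-even to ``decimals`` places.
    """
    n_state = len(rows[0].state) if rows else 6
    n_action = len(rows[0].action) if rows else 5
    header = (
        ["n_cases"]
        + [f"i{k}" for k in range(1, n_state + 1)]
        + [f"a{k}" for k in range(1, n_action + 1)]
        + ["expected_reward", "total_value"]
    )
    lines = ["\t".join(header)]
    for r in rows:
        cells = [str(r.n_cases), *r.state, *r.action]
        cells.append(f"{r.expected_reward:.{decimals}f}")
        cells.append(f"{r.total_value:.{decimals}f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str
    out_dir: str
    column_map: dict[str, str] = field(default_factory=dict)
    score_schema: ScoreSchema = field(default_factory=default_score_schema)
    min_count: int = 10
    horizon: int = 2
    span: int = 2
    tie_break: str = "lexicographic"
    decimals: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")
        if self.horizon < 2:
            raise ValidationError("horizon must be >= 2")
        if self.tie_break != "lexicographic":
            raise ConfigurationError(
                f"unknown tie-break rule {self.tie_break!r} (only 'lexicographic')"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort_path" not in doc or "out_dir" not in doc:
            raise ConfigurationError("config needs at least cohort_path and out_dir")
        schema = (
            ScoreSchema.from_dict(doc["score_schema"])
            if "score_schema" in doc
            else default_score_schema()
        )
        return cls(
            cohort_path=str(doc["cohort_path"]),
            out_dir=str(doc["out_dir"]),
            column_map=dict(doc.get("column_map", {})),
            score_schema=schema,
            min_count=int(doc.get("min_count", 10)),
            horizon=int(doc.get("horizon", 2)),
            span=int(doc.get("span", 2)),
            tie_break=str(doc.get("tie_break", "lexicographic")),
            decimals=int(doc.get("decimals", 3)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class RunReport:
    """What happened in a pipeline run — nothing is excluded silently."""

    n_records_read: int
    missingness_pct: dict[str, float]
    n_cells_imputed: dict[str, int]
    exclusions: dict[str, int]
    n_records_modeled: int
    filter: FilterReport
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "n_records_read": self.n_records_read,
            "missingness_pct": {k: round(v, 4) for k, v in sorted(self.missingness_pct.items())},
            "n_cells_imputed": dict(sorted(self.n_cells_imputed.items())),
            "excluded_records": dict(sorted(self.exclusions.items())),
            "n_records_modeled": self.n_records_modeled,
            "state_filter": self.filter.to_dict(),
            "outputs": dict(sorted(self.outputs.items())),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _missingness_pct(records, schema: ScoreSchema) -> dict[str, float]:
    """Percentage of missing cells per item (across timepoints) and per
    characteristic, before imputation."""
    out: dict[str, float] = {}
    n = len(records)
    if n == 0:
        return out
    for ch in ("i1", "i2", "i3", "i4", "i5"):
        out[ch] = 100.0 * sum(r.characteristics.get(ch) is None for r in records) / n
    for item in schema.item_names:
        miss = sum(
            r.item_scores[t].get(item) is None for r in records for t in (1, 2, 3)
        )
        out[item] = 100.0 * miss / (3 * n)
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute read -> impute -> episodes -> filter -> fit -> solve -> report.

    Writes the episode TSV, model/policy/value JSON, the two stage tables
    and a JSON run report into ``config.out_dir``, and returns the report.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = config.score_schema

    records = read_cohort(config.cohort_path, schema, config.column_map or None)
    logger.info("read %d records from %s", len(records), config.cohort_path)
    missing_pct = _missingness_pct(records, schema)
    records, imputed = impute_cohort(records, schema, span=config.span)
    episodes, exclusions = build_episodes(records, schema)
    model, filter_report = fit_mdp(
        episodes, min_count=config.min_count, horizon=config.horizon
    )
    policy, values = backward_induction(model)

    outputs: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        outputs[name] = str(path)

    _save("episodes.tsv", lambda p: write_episodes(episodes, p))
    _save("model.json", model.save)
    _save("policy.json", policy.save)
    _save("values.json", values.save)
    for stage in model.stages():
        rows = policy_table(policy, values, model, stage)
        _save(
            f"stage{stage}_policy.tsv",
            lambda p, rows=rows: Path(p).write_text(
                format_policy_table(rows, config.decimals)
            ),
        )

    report = RunReport(
        n_records_read=len(records),
        missingness_pct=missing_pct,
        n_cells_imputed=imputed,
        exclusions=dict(exclusions),
        n_records_modeled=filter_report.n_records_after,
        filter=filter_report,
        outputs=outputs,
    )
    report.save(out_dir / "run_report.json")
    report.outputs["run_report.json"] = str(out_dir / "run_report.json")
    return report
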