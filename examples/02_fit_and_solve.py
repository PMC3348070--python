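"""Fit the two-stage treatment MDP from a cohort and print the optimal
stage-1 treatment table.

Pipeline: generate -> impute missing items (nearby-median) -> extract
state-action-reward episodes -> filter states with fewer than 10 records ->
estimate transition/reward tables from counts -> backward induction.
"""

from stroke_mdp import (
    backward_induction,
    build_episodes,
    default_cohort_spec,
    fit_mdp,
    format_policy_table,
    generate_cohort,
    impute_cohort,
    policy_table,
)

spec = default_cohort_spec(n_patients=960, seed=1)
records, _truth = generate_cohort(spec)
records, _ = impute_cohort(records, spec.score_schema)
episodes, exclusions = build_episodes(records, spec.score_schema)
model, report = fit_mdp(episodes, min_count=10)
policy, values = backward_induction(model)

print(f"episodes: {len(episodes)}; excluded records: {dict(exclusions)}")
print(f"states retained: {len(report.retained)}; dropped (support < 10): {len(report.dropped)}")
rows = policy_table(policy, values, model, stage=1)
print("\nstage-1 optimal treatment combinations (top 5 by support):")
print(format_policy_table(rows[:5]))
# Each row: case count, the six state digits (age band, history,
# complication, TCM diagnosis, TCM pattern, severity level), the five
# digits of the best treatment combination, the expected immediate reward
# u_1(i, f_1(i)) and the total two-stage value J_1(i) in score units
# (positive = expected improvement).
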