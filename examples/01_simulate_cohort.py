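"""Generate a synthetic 960-patient stroke cohort and inspect its makeup.

The default specification reproduces the reference admission composition
(age bands, disease history, TCM patterns, severity levels) and the
reported per-item missingness rates; the generator also returns the exact
ground-truth MDP the cohort was drawn from.
"""

from collections import Counter

from stroke_mdp import default_cohort_spec, generate_cohort

spec = default_cohort_spec(n_patients=960, seed=1)
records, truth = generate_cohort(spec)

ages = Counter(r.characteristics["i1"] for r in records)
patterns = Counter(r.characteristics["i5"] for r in records)
n_missing_ataxia = sum(
    r.item_scores[t]["ataxia"] is None for r in records for t in (1, 2, 3)
)

print(f"patients: {len(records)}")
print(f"aged 46-65 / >66: {ages[2]} / {ages[3]}  (reference: 308 / 652)")
print(f"Yang / Yin pattern: {patterns[1]} / {patterns[2]}  (reference: 305 / 601)")
print(f"missing ataxia cells: {n_missing_ataxia} of {3 * len(records)} "
      f"({100 * n_missing_ataxia / (3 * len(records)):.1f}%; reference rate 18.39%)")
print(f"ground-truth states: {len(truth.model.states())}, "
      f"stage-1 (state, action) pairs: {len(list(truth.model.transitions.pairs(1)))}")
# Counts close to the reference proportions (they are binomial draws) show
# the cohort has the intended marginal composition.
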