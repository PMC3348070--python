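# stroke-mdp

Finite-horizon Markov decision processes for comparing the effectiveness of
treatment *combinations* in hospitalized acute-ischemic-stroke cohorts.

Routine stroke care mixes several therapies at once — antiplatelet or
anticoagulant agents, pattern-specific Traditional Chinese Medicine
treatments (Yi Qi Wen Yang for the *Yin* pattern, Qing Re Xi Feng for the
*Yang* pattern), bowel-relaxing treatment, herbal medicine — and the mix is
adjusted as the patient's condition evolves. Randomized trials compare
whole protocols; they cannot rank the combinations stage by stage. This
package implements the alternative: treat each hospitalization record as a
short sequential decision problem and estimate, from observational records
alone, which combination maximizes the expected total improvement from each
patient condition onward.

It is a library first (everything is importable from `stroke_mdp`; see
`examples/` for narrative scripts), with a thin `stroke-mdp` CLI for
running the pipeline from a shell.

## The model

A hospital stay is split at admission (*t1*), day 3 (*t2*) and discharge
(*t3*) into two treatment stages. The patient **state**
`i = (i1,…,i6)` collects age band, disease history, complications, TCM
diagnosis, TCM pattern, and the severity level of a 0–29 neurological
impairment score (levels band the score as 0–2, 3–5, 6–12, 13–19, 20–29;
death is recorded as the maximal score 29). The **action**
`a = (a1,…,a5)` is the 5-flag treatment combination. The **reward** of a
stage is the score before it minus the score after it (positive =
improvement). States and actions are handled as digit strings
(`"200111"`, `"01011"`).

From the extracted episodes, states with fewer than 10 records are
dropped, and the non-stationary tabular MDP
`{S, A_t(i), p_t(j|i,a), u_t(i,a)}` is estimated by counting:

- `p_t(j|i,a) = #(j,i,a) / Σ_j' #(j',i,a)`,
- `u_t(j,i,a)` = mean observed reward of the transition, and
  `u_t(i,a) = Σ_j p_t(j|i,a) u_t(j,i,a)`,
- `A_t(i)` = the combinations actually observed for `i` at stage `t`.

With a zero terminal reward, backward induction

```
J_t(i) = max_{a ∈ A_t(i)} [ u_t(i,a) + Σ_j p_t(j|i,a) J_{t+1}(j) ]
```

yields the optimal decision rules `f*_t(i)` and values `J_t(i)`, reported
as per-stage policy tables. A brute-force policy-enumeration oracle, an
exhaustively testable synthetic-cohort generator with an exactly known
ground-truth MDP, and an effect-planting device for policy-recovery checks
are part of the package, so every stage is verifiable without any
external data.

## Worked example

```python
from stroke_mdp import (
    default_cohort_spec, generate_cohort, impute_cohort, build_episodes,
    fit_mdp, backward_induction, policy_table, format_policy_table,
)

spec = default_cohort_spec(n_patients=960, seed=1)   # reference composition
records, truth = generate_cohort(spec)
records, _ = impute_cohort(records, spec.score_schema)
episodes, _ = build_episodes(records, spec.score_schema)
model, report = fit_mdp(episodes, min_count=10)
policy, values = backward_induction(model)
print(format_policy_table(policy_table(policy, values, model, stage=1)[:5]))
```

prints (this is `examples/02_fit_and_solve.py`):

```
n_cases	i1	i2	i3	i4	i5	i6	a1	a2	a3	a4	a5	expected_reward	total_value
136	3	1	0	1	2	1	0	0	0	1	1	2.000	2.067
95	3	1	0	1	2	2	0	1	0	1	1	5.000	5.067
76	3	1	0	1	1	1	1	1	1	0	0	2.000	3.000
64	3	1	0	1	1	2	0	1	0	0	1	-3.000	5.000
57	3	1	0	1	2	3	0	0	0	0	1	3.000	8.000
```

Each row is one retained patient condition, ordered by case count: the six
state digits, the five digits of the optimal treatment combination, the
expected immediate reward `u_1(i, f*_1(i))` and the total two-stage value
`J_1(i)`, both in score units (positive = expected improvement). The first
row reads: for 136 patients aged over 66 with a disease history, no
complications, channels/collaterals diagnosis, *Yin* pattern and mild
impairment, bowel-relaxing treatment plus herbal medicine maximized the
expected improvement (2.0 points now, 2.067 over both stages).

The same pipeline runs from a shell:

```sh
stroke-mdp simulate --n 960 --seed 1 --out sim/
stroke-mdp run --cohort sim/cohort.csv --min-count 10 --out results/
```

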