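# Methods

## The decision model

A hospitalization record is segmented at admission (t1), day 3 (t2) and
discharge (t3) into two state–action–reward stages. The state is the
6-digit code `(i1..i6)` — age band, any disease history, any complication,
TCM diagnosis, TCM pattern, neurological-function level — and the action
is the 5-flag treatment combination `(a1..a5)`. The neurological-function
level bands a 0–29 impairment score (0–2, 3–5, 6–12, 13–19, 20–29); a dead
patient scores 29, so death enters the state space as maximal severity and
needs no separate bookkeeping. The stage reward is the score before the
stage minus the score after it; rewards therefore telescope to
`score(t1) − score(t3)` within a record, and a zero terminal reward makes
the two-stage total the optimization criterion.

`i1..i5` are treated as constant over the stay and only the severity level
varies by timepoint. Episodes from the same patient are treated as
independent samples — the usual tabular-MDP simplification; within-patient
correlation across stages is not modeled.

The fitted model is the non-stationary finite-horizon tuple
`{S, A_t(i), p_t(j|i,a), u_t(i,a)}` with `horizon = 2` decision stages.
Throughout the package `horizon` counts decision stages; stage
`horizon + 1` carries only the terminal reward.

## Estimation

Transition probabilities are raw count ratios per stage; per-transition
rewards are arithmetic means of observed episode rewards; expected rewards
are the probability-weighted sums, which algebraically equal the pooled
mean reward of the (stage, state, action) cell. No smoothing, shrinkage or
covariate adjustment is applied: a probability is positive only where a
transition was observed, and the admissible action set of a state is
exactly the set of combinations observed for it at that stage (the two
stages may differ).

Support filtering precedes estimation: a state is retained only if at
least `min_count` (default 10, inclusive) distinct records *start* in it,
and dropping a record removes both of its episodes. Next states are not
filtered; a next state without support at the following stage contributes
its terminal reward as continuation value during backward induction
(dropping its probability mass would break row normalization), and each
such fallback is logged.

## Solving

Backward induction maximizes `u_t(i,a) + Σ_j p_t(j|i,a) J_{t+1}(j)` per
stage and state. Ties in the argmax are broken by the lexicographically
smallest action code, making the solution deterministic. The brute-force
oracle enumerates every admissible policy (capped at 10^6), evaluates each
from every state, and returns the per-state maxima plus the
lexicographically smallest policy attaining all stage-1 maxima; it exists
purely as an independent check of the recursion and is never the
production path.

Published per-state "reward" columns are ambiguous between the chosen
action's immediate expected reward and the total value; the stage tables
therefore print both (`expected_reward` = `u_t(i, f*_t(i))`,
`total_value` = `J_t(i)`), rounded half-to-even to 3 decimals (stored at
full precision; tables are views recomputable from the model JSON).

## Missing data

Missing cells are imputed column-wise by the median of nearby points:
records are ordered by admission date then record id, and each gap takes
the median of up to `span` (default 2) non-missing neighbours on each side
in that ordering; imputed item values are rounded half-to-even back to
integers. The ordering is fixed so results are deterministic. State
characteristics are imputed the same way; missing treatment flags are
never imputed — the record is excluded and counted in the run report, as
are records dead on admission. Nothing is excluded silently.

The shipped impairment instrument (nine NIHSS-style items with maxima
5,2,2,5,5,2,2,3,3 summing to 29) is a configurable stand-in with the right
structure, not any hospital's exact scale; pass a custom `ScoreSchema` to
use a real one.

## The synthetic cohort generator

The generator emulates what the analysis assumes about real cohorts:

- **Admission composition.** Independent per-component marginals; defaults
  reproduce the reference cohort (308/652 aged 46–65/>66, 252/708 disease
  history, 18/960 complications, all channels/collaterals diagnosis,
  305/601/38/16 Yang/Yin/composite/other patterns, severity levels
  402/355/203 in levels 1–3). Joint structure beyond the marginals is not
  claimed by the source data and is off by default.
- **Treatment assignment.** Per-flag Bernoulli draws: pattern-matched TCM
  treatment with probability 0.85 (0.10 otherwise), bowel-relaxing
  treatment 0.90 for a persistent latent constipation indicator
  (prevalence 0.30; 0.08 otherwise), antiplatelet/anticoagulant 0.92 and
  herbal medicine 0.95. The exception rates are unquantified in the source
  setting; these are documented package defaults chosen once. A living
  patient is never assigned the all-zero combination (herbal medicine is
  forced on instead); the all-zero code is reserved for the dead, keeping
  the absorbing state's action set disjoint from treatment.
- **Outcomes.** A latent integer score change drawn from a discretized
  Gaussian (truncated at ±6σ) whose mean is a per-level baseline plus
  bonuses for pattern-matched TCM treatment, antiplatelet agents and
  herbal medicine; the new score is clipped to [0, 29]. Death occurs with
  a per-stage, per-level probability (defaults put ≈0.5% of a cohort dead
  during stage 2, none in stage 1) and is absorbing at score 29.
- **Missingness.** Independent per-item masking; defaults match the
  reported rates (ataxia 18.39%, visual field 13.80%, sensory 13.76%,
  others 0.07–7.11%).

Two deliberate choices make the severity process *exactly* Markov with an
analytically computable kernel, so recovery tests have an exact estimand:
the latent change is sampled from the same finite discretized distribution
the analytic kernel integrates over, and after the change selects the next
severity band the realized score is re-drawn uniformly within that band.
The within-band score distribution is then uniform at every timepoint
regardless of history. The cost is that the realized score-change
distribution is not literally the latent Gaussian; the gain is that
`ground_truth_mdp` returns the exact transition kernel, expected rewards
(`E[s|j] − mid(band_j)`, and `mid(band_i) − 29` for death) and optimal
policy implied by a spec. What passing recovery tests therefore show is
that the pipeline consistently estimates a cohort whose state process
genuinely is Markov in the coded state; they cannot show robustness to
non-Markov dynamics, unmeasured confounding, or instrument misspecification
in real records.

A single root seed drives independent substreams for demographics,
assignment, outcomes, item allocation and missingness; identical spec and
seed give bit-identical cohorts.

## Effect planting and recovery measurement

`plant_effect_gap(spec, gap)` separates one designated pattern-concordant
action per state (`a1=1`, matched TCM flag, `a4=0`, `a5=1`) from all
alternatives by at least `gap` score units of true Q-value at both stages.
The separation is achieved by *penalising* non-designated outcome means
(deterioration): downward room in the score range always exists, whereas
improvement clips at score 0 for mild states. The penalty is found by a
verification loop that rebuilds the exact ground truth and checks every
treatable state's Q-gap; if no penalty within the score range achieves the
gap, a validation error is raised. Maximal-severity (level 5) states are
excluded from the guarantee: from the top band outcomes can hardly worsen,
so no outcome-mean penalty can separate actions arbitrarily there, and
those states carry essentially no treatable support.

Recovery is measured on well-supported cells: a (stage, state) counts when
the designated action has ≥ 50 episodes there, and the comparison argmax
runs over actions with ≥ 50 episodes each (`support_restricted_policy`).
An action observed a handful of times has a reward-estimate standard error
of several score units, so an unrestricted argmax can be beaten by a
1-episode arm by chance regardless of the planted gap; restricting the
comparison to adequately observed arms is what makes "did the pipeline
find the planted optimum?" a well-posed question. The unrestricted solved
policy is always available alongside.

## Problem sizes and checks

The shipped end-to-end checks use: 200 random instances (≤ 5 states, ≤ 4
actions, 2–3 decision stages) for solver-vs-enumeration agreement at
1e-9; a 2,000-patient cohort plus an adversarial hand-built fixture for
the estimator identities (row sums within 1e-12, expected-reward identity
within 1e-9); 50,000 patients on a concentrated-support spec — one
demographic stratum, three severity levels closed under the truncated
outcome noise, two treatment arms, so every cell carries thousands of
episodes — for transition recovery within 0.02 on cells with true
probability ≥ 0.05 (under the full reference marginals thin cells have
binomial noise far above 0.02, so that check would measure sample size,
not correctness); 20,000 patients with a planted 3-point gap for ≥ 95%
designated-action recovery; and a 960-patient reference-scale run for
table structure and filter reporting. Planted and recovery fixtures are
generated without missingness to isolate estimation from imputation;
imputation robustness has its own check (≤ 20% missingness on two items
changes the recovered policy on ≤ 10% of common states).

## Known limitations

- Observational confounding is not addressed: like the estimator it
  mirrors, the pipeline compares outcomes among treatments *as assigned*.
  The generator's assignment depends only on coded state and an
  independent latent, so synthetic checks cannot surface
  confounding-by-indication.
- Only two decision stages are exercised end to end (the solver itself is
  generic in the horizon).
- Admissible sets are the observed ones; rarely observed actions enter the
  argmax with noisy values (hence the support-restricted comparison for
  recovery metrics).
- The nearby-median imputation is a deterministic single imputation; no
  uncertainty from imputation propagates into the values.
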