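# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `prlfit`. It is the package's own account of what it
computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py` at run time.

## The task

The probabilistic reversal learning (PRL) task is a two-alternative bandit
of `n_trials = 120` trials. One stimulus is *advantageous* — it rewards a
choice with probability `p_reward_advantageous = 0.8` — and the other
*disadvantageous* (`p_reward_disadvantageous = 0.2`). After trial
`reversal_trial = 60` the roles swap silently. Trials 1–60 form the
acquisition phase, 61–120 the reversal phase. The two stimuli's outcome
streams are independent: on a given trial both, one or neither stimulus may
carry a reward, since the contingencies are defined per stimulus rather
than anti-correlated. Rewards are coded `R ∈ {1, 0}`.

Two schedule modes are supported. The default `exact_ratio` mode pre-draws
each (phase × stimulus) cell so that the advantageous stimulus carries
exactly `0.8 · 60 = 48` rewards per phase in a seeded random order,
matching a fixed frequency-ratio design; `bernoulli` draws every trial
independently. Schedules with a non-integer expected reward count per phase
are rejected in `exact_ratio` mode rather than silently rounded.

A *missed* trial (no response inside the task's response window) carries no
choice and no outcome. The simulators emit misses independently per trial
with probability `miss_probability`; this is a deliberate simplification —
real misses likely cluster with fatigue or motor load, which the generator
does not model.

**Phase scores.** The score of a phase is the count of rewarded trials in
it. This is the one scoring rule the package implements; counting
advantageous choices instead would give similar but not identical values,
and the reward count is the definition consistent with the magnitudes such
studies report (e.g. acquisition means near 42 of 60). Missed trials score
zero.

## Candidate strategies and likelihoods

Three generative models describe a subject's trial-by-trial choices.

**Q-learning.** Action values for the two stimuli start at
`q_init = 0.5` each (the neutral midpoint of the reward coding; the value
is configurable) and the chosen stimulus's value is updated by the
delta rule

    Q_s(t+1) = Q_s(t) + α (R(t) − Q_s(t)),

with learning rate `α ∈ [0, 1]`. Choice follows the softmax

    P(a(t) = 1) = 1 / (1 + exp(−β (Q_1(t) − Q_2(t)))),

with inverse temperature `β ≥ 0`; `β = 0` is uniform choice, large `β`
near-deterministic exploitation. The log-likelihood of a sequence is the
sum of log choice probabilities over valid trials.

**Win-stay/lose-shift (WSLS).** Two parameters: `P(stay|win)`, the
probability of repeating the previous choice after a reward, and
`P(shift|lose)`, the probability of switching after a non-reward. A trial
with no valid predecessor contributes `ln ½`.

**Random.** Uniform choice; zero parameters; `LL = n_valid · ln ½` in
closed form.

**Missed trials** contribute nothing to any likelihood and carry no model
update: no action–outcome pair was observed, so the Q-values are frozen
across the gap and the WSLS one-trial memory is erased (the next trial is
treated as having no predecessor). Both conventions are applied
consistently in the simulators and the likelihoods.

## Fitting and strategy classification

Q-learning parameters are estimated by maximum likelihood with bounded
multi-start local optimisation: L-BFGS-B from `n_restarts = 10` seeded
Latin-hypercube starts over `[0, 1] × [0, β_max]`, convergence tolerance
`1e-6`. `β_max = 50` comfortably covers empirically plausible values
(group SDs near 7 imply occasional fits past 20). The log-likelihood is
evaluated through a softplus formulation, so the objective stays finite
and smooth even when the softmax saturates; fits pinned at a bound are
flagged (`at_bound`) rather than rejected. The standing test suite checks
the optimiser against a brute-force grid oracle (α step 0.02, β step 0.25
up to 20) on 50 simulated sequences, at a 1e-3 nat tolerance.

The WSLS MLE is computed in closed form from transition counts —
`P(stay|win)` is the fraction of rewarded trials (followed by a valid
trial) on which the choice repeated, and analogously for `P(shift|lose)`.
A ratio with no informative transitions defaults to 0.5, which leaves the
likelihood unchanged. Equivalence to numerical optimisation is asserted by
a grid test, not offered as an option.

Each model is scored by `AIC = −2·LL + 2k` with `k = 2` (Q-learning), `2`
(WSLS) and `0` (random), and the subject is labelled with the
AIC-minimising strategy. Exact ties are measure-zero but broken
deterministically by parsimony then simplicity: random ≺ WSLS ≺
Q-learning.

Simulation studies at the task's default length (120 trials) put the
method's resolution on record: rank correlations between generating and
fitted parameters of roughly 0.85 for both α and β (200 agents, α ~
U(0.1, 0.9), β ~ U(1, 10)), and strategy-recovery rates of ~100% for
Q-agents at (0.4, 4), ~100% for sticky WSLS agents (0.95/0.95), and ~80%
for random agents — random data can be mildly overfitted by the
two-parameter models, so a minority of truly random subjects are
mislabelled even with the AIC penalty.

## The selection funnel

Cohort analysis begins with a three-stage exclusion procedure, applied in
a fixed order; subjects are flagged, never deleted, and each exclusion
records only the first rule that fired.

1. **Score filter.** Thresholds are the control-group mean minus
   `1.5 × SD` of the phase score, computed over *all* controls before any
   exclusion. The acquisition filter applies to both groups (a low
   acquisition score suggests the task was not understood); the reversal
   filter applies to controls only, selecting controls who performed the
   task successfully without discarding patients whose reversal behaviour
   is the phenomenon of interest. Both scopes are configurable, since the
   design is genuinely ambiguous. Comparisons are strict (`score <
   threshold` excludes).
2. **Strategy filter.** Subjects whose AIC-best model is not Q-learning
   are excluded: WSLS and random choosers generate choices by a different
   process, so their (α, β) fits are not interpretable.
3. **β-outlier filter.** Controls with fitted `β` more than 3 SD above the
   mean of the surviving controls are excluded (controls only by default,
   configurable): an extreme-β control is an outlier, whereas extreme β in
   the case group is the phenotype itself.

## The Pαβ discriminant, ROC and classification

On the included subjects, a logistic regression of group (case = 1) on the
fitted (α, β) yields

    Pαβ = 1 / (1 + exp(−(b₀ + b₁ α + b₂ β))),

the probability that a subject's parameter pattern is case-like. The
model is fitted by maximum likelihood (statsmodels); complete or
quasi-complete separation is detected and flagged, with a weakly
regularised fallback, rather than silently reporting diverged
coefficients. Nested α-only / β-only / α+β fits are compared by
`AIC = −2·LL + 2k` with k counting intercept plus slopes, consistent with
the per-subject strategy AIC.

A *replication mode* scores subjects with a stored published coefficient
set, `Pαβ = 1/(1 + e^{0.742 + 1.263α − 0.245β})` (stored internally in
standard orientation: intercept −0.742, slopes −1.263 and +0.245, with a
serialiser that reproduces the printed form), together with its published
cutoff 0.512. Under these coefficients Pαβ is strictly decreasing in α
and increasing in β; at the reference group-mean parameter points it
evaluates to 0.6443 (α = 0.3, β = 7.0) and 0.4336 (α = 0.4, β = 4.0),
which bracket the cutoff.

The ROC curve is computed empirically over all distinct score values, with
a subject called positive when its score *strictly exceeds* the threshold.
AUC is the trapezoid integral, which equals the Mann–Whitney pairwise
concordance probability with ties counted ½ — an identity the tests check
exactly against a brute-force oracle. The operating cutoff maximises
Youden's J = sensitivity + specificity − 1 ("most efficient
discrimination" is operationalised as Youden's criterion; ties take the
lowest cutoff). Classification uses strict inequality: a subject exactly
at the cutoff is *typical*.

Group summaries use the two-sided Mann–Whitney U test for numeric
variables and the chi-squared test for categorical ones, with unadjusted
p-values (no multiple-testing correction, matching the descriptive use of
these tables).

## The synthetic cohort generator

No subject-level choice data are publicly deposited for this paradigm, so
the generator emulates the *distributional* facts such a study reports,
with defaults frozen at the documented study conditions:

- group sizes 63 control / 62 case;
- Q-learning parameters drawn from truncated normals with the reported
  group moments — control α ~ N(0.4, 0.3²), β ~ N(4.0, 1.7²); case α ~
  N(0.3, 0.3²), β ~ N(7.0, 7.1²) — truncated to α ∈ [0, 1] and β ∈
  [0.1, 50]. The β floor keeps nominal Q-subjects from being pure-noise
  choosers that would be labelled random by construction. With the case
  group's large SD the truncation shifts the realised β mean above 7;
  tests compare sample means against the truncated-normal moment computed
  by an independent oracle, not against the raw location parameter. A
  log-normal would be an equally defensible model of the heavy right tail;
  truncated-normal was chosen as the minimal reading of a mean ± SD
  summary.
- a strategy mix of 62% Q-learning, 19% WSLS, 19% random per group,
  mirroring the reported screening proportions (≈61% of subjects
  Q-classified; the WSLS:random split is unreported and is set even);
  WSLS parameters drawn uniformly from [0.55, 0.95];
- `miss_probability = 0.05`, the miss rate implied by a reported example
  subject with 114 of 120 valid trials.

All randomness descends from a single spec-level seed through spawned
per-subject seeds, so cohorts regenerate byte-identically and any subject
can be re-simulated in isolation.

What passing on these cohorts does **not** show: the generator draws
(α, β) independently per subject, misses uniformly at random, and makes
every subject stationary within the task. Real cohorts have
parameter–covariate correlations, non-stationary attention, and
response-time structure, none of which are modelled; results on synthetic
cohorts certify the pipeline's statistical machinery, not clinical
validity.

A six-subject worked fixture (two typical Q-controls, two high-β/low-α
Q-cases, one WSLS, one random subject, simulated miss-free under pinned
seeds) exercises every pipeline branch; its full set of outputs is
committed and must regenerate byte-exactly.

## Problem sizes and determinism

The standing simulation studies use 120-trial sequences throughout —
the task's own length — with 200 agents per recovery study, 50 sequences
per optimiser-vs-grid audit, 50 replicates of the logistic
coefficient-recovery study (≈1000 subjects each), and a 60-per-group
cohort for the end-to-end funnel check. These sizes give stable Monte
Carlo estimates for the properties asserted while keeping a full run of
the suite inside a coffee break. Every stochastic component takes an
explicit seed; fits, pipelines and generators are bit-reproducible.

## Known limitations

- Single learning rate: differential learning from positive and negative
  prediction errors is not modelled, nor is choice-trace perseverance or
  a WSLS–RL dual-process mixture; these are documented extensions, and
  the strategy set here is the standard three-way screen.
- The logistic discriminant is a two-predictor linear model on (α, β);
  any nonlinear boundary between groups is out of scope.
- Fitted β is right-skewed at the task's length; mean fitted β can exceed
  the generating mean appreciably for high-β subjects (bounded above by
  `β_max`). Medians and rank statistics are the robust summaries, and the
  group comparison test is rank-based for this reason.
- The per-trial uniform miss model understates the autocorrelation of
  real misses.
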