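# Methods

## Task environment

The environment is an `n_rows × n_cols` grid of rooms (default 5×5, fully
connected by doors between orthogonal neighbours). An agent's state is the
pair (room, entry direction); leaving through the door just entered is
forbidden, so an entered interior room offers three actions, an edge room
two and a corner room one. At a trial's first step no entry direction
exists and every door is available — the task gives no initial facing, so
the least-assumption choice is to exclude nothing. Coordinates are 0-based
(row, col) with row 0 the north edge; actions are absolute compass moves,
and all state–action tables are indexed (room, direction), i.e. 25 states
with up to 4 (effectively ≤ 3) actions.

A session has three phases. Encoding: 8 trials from a fixed start, each
collecting three rewards in a fixed order; a trial therefore decomposes
into three *legs* (start→R1, R1→R2, R2→R3), and the entry direction carries
across leg boundaries because the agent keeps moving. Retrieval: 15 trials
from the same start, one uniformly drawn target each. Search: 15 trials
(count configurable; the task description does not fix it, so it mirrors
retrieval) with one target and a start drawn from the non-reward rooms,
never equal to the target and never repeating the previous trial's start.

The default layout places the start at (4,0) and the ordered rewards at
(0,2), (2,4), (4,2): three well-separated rooms, 6/4/4 optimal steps
between consecutive targets. The layout is configurable (YAML) and all
results here are qualitative with respect to it.

## Choice models

**Model-free.** SARSA(λ) with replacing eligibility traces, one
independent table per reward context (no interference between targets).
For step *i* of a leg: δ = R + Q_MF(s′,a′) − Q_MF(s,a) with the *actually
taken* next action a′ and successor value 0 at the terminal (rewarded)
step; the visited pair's trace is set to 1, all pairs move by α·δ·z, all
traces decay by λ. There is no temporal discount in δ. Traces reset at
each leg start and never carry across trials. Updates are on-policy and
online: a step's update can only be applied once the next action is known,
so it lands after that choice; the terminal update lands on reward receipt.
The likelihood replay reproduces exactly this order, which makes replayed
choice probabilities agree with the simulator's to machine precision.

**Model-based.** The planner knows the maze and solves
Q_MB(s,a) = R(s′) if s′ is the reward room, else (1−γ)·max over the
successor's legal continuations (backtrack excluded, mirroring the
environment; if a successor had no continuation its value is 0). γ = 0.1
is fixed, not fitted; R = 1 per target (the scale is absorbed by β).
Synchronous sweeps from all-zero values with tolerance 1e-12 and max_iter
500 reach the fixed point in 8 sweeps on the default maze. The fixed point
has the closed form Q_MB(s,a) = (1−γ)^(d−1)·R where d is the length of the
shortest no-backtracking route from s through a to the reward; this serves
as an exhaustive oracle in the tests. Q_MB does not depend on trial or
step.

**Hybrid and choice rule.** Q_hybrid = (1−ω)·Q_MF + ω·Q_MB, softmax
p(a) ∝ exp(β·Q) over the legal actions only, stabilised by max
subtraction. ω = 0 and ω = 1 are the pure models.

## Synthetic cohorts

Subjects are simulated from the hybrid model; pure strategists are the
ω endpoints. Default parameter sampler: α ~ U[0.1, 0.9], β ~ U[1, 10],
λ ~ U[0, 1], ω ~ U[0, 1], independent per subject. Model-free values
persist across phases during simulation (one continuous session), while
fitting re-initialises them per phase to match per-phase parameter
estimates; both behaviours are switchable, and the carry-over question is
genuinely open since per-phase fitting does not determine what the subject
retained. A 200-step cap per leg flags pathological legs as truncated
(warning; excluded downstream); at the default parameters truncation is
rare enough that no run in the test suite hits it except by construction.

What the generator does *not* emulate: perceptual room confusion,
forgetting, reaction times, any within-trial deliberation dynamics, or
heterogeneity beyond independent uniform parameters. Passing tests
therefore validate the estimation machinery on data generated by the
assumed model, not the model's adequacy for human behaviour.

## Navigation indices

Shortest paths are breadth-first-search distances on the
(room, entry-direction) graph, honouring the backtrack exclusion and using
the leg's actual entry state (trial starts have no entry constraint; on
the full default grid the fresh-start optimum equals the Manhattan
distance). Per trial, observed and optimal steps are summed over legs.

I_PATH is the fraction of trials with observed = optimal steps. I_STEPS
uses phase-summed steps with n_max_steps the worst per-phase total across
the cohort — it is a relative, cohort-dependent quantity; a degenerate
cohort (everyone optimal) yields 1 with a warning. I_ROUTE counts a trial
as a route repetition when at least 60% of its directed room-to-room
transitions occur in the subject's reference route for that context,
defined as the *final* encoding leg (the stabilised route; earlier
repetitions are still exploratory). Overlap is computed on directed
transitions, not room sets, because routes are directional. A trial that
is both shortest and route-overlapping counts as shortest, so a perfect
planner scores I_ROUTE = 0. When a phase has neither route nor shortest
trials I_ROUTE is undefined (NaN, warning) and is skipped by the
across-phase average; the averaged index is the arithmetic mean of the
three phase values.

## Fitting

Per subject × phase, penalised maximum likelihood: the replayed choice
log-likelihood plus log-priors α, λ, ω ~ Beta(1.2, 1.2) and
β ~ Gamma(shape 2, scale 3) — weakly informative regularisers that keep
boundary estimates finite, standing in for a full hierarchical scheme. An
optional empirical-Bayes pass moment-matches the hyperparameters from the
cohort's MAP estimates and refits once; priors can be switched off for
pure ML. Optimisation is L-BFGS-B from 10 Latin-hypercube starts (the
likelihood is mildly multimodal in α and λ), boxes α, λ, ω ∈
[1e-4, 1−1e-4], β ∈ [1e-3, 30], objective tolerance 1e-8, best restart
wins; identical seeds give identical fits. Model variants: model-free
(k = 3), model-based (k = 1, β only — its values need no learning),
hybrid (k = 4). AIC = 2k + 2·NLL and BIC = k·ln(n) + 2·NLL use the
unpenalised NLL at the MAP estimate; comparison ties break toward fewer
parameters. Slices with fewer than 10 choices are refused.

The replay kernel is compiled (numba) because it sits in the optimiser's
inner loop: a cohort of 27 subjects × 3 phases fits in roughly 10 s on one
CPU at 10 restarts. All study-scale analyses in the tests use 27 subjects
and 8/15/15 trials; the recovery and sign-pattern checks run 10 cohort
seeds (~2 min total).

## Known limitations and observed model behaviour

* **ω–optimality coupling is weak and non-monotone.** The planning values
  decay as (0.9)^d with distance d, so far from the reward the value gap
  between the best and second-best door is small; at β ≤ 8 a *pure*
  planner chooses only weakly better than chance there, while learned
  route values (≈1 vs 0) are sharp. Measured consequence (20 seeds,
  β = 5): mean excess steps over ω ∈ {0, .25, .5, .75, 1} are
  6.6, 5.5, 5.3, 5.7, 7.1 — hybrid agents are the most efficient, and a
  pure planner can be *less* optimal than a route learner. Across a
  cohort with independent uniform parameters, β dominates optimality and
  corr(ω, I_PATH) is near zero; only the negative ω–I_ROUTE relation is
  robust. A strong positive ω–I_PATH correlation therefore should not be
  expected from this generative model at moderate β, even though fitted ω
  itself is well recovered (r ≈ 0.86 median at study scale). The unit
  suite asserts the properties that do hold: a sharp (β = 50) pure
  planner is exactly optimal, and at β = 8 an ω = 0.5 hybrid beats an
  ω = 0 route learner on excess steps.
* α and λ recover weakly at study-scale trial counts (reported, not
  asserted); ω is the identifiable quantity.
* I_STEPS is cohort-relative by definition; comparing it across cohorts
  of different composition is not meaningful.
* The model-based agent assumes perfect knowledge of the maze from the
  first trial; there is no map-learning phase.
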