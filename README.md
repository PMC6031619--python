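# gridnav

Reinforcement-learning analysis of wayfinding behaviour in a grid world.

People navigate either by repeating learned routes (a sequence of turns that
previously led to the goal) or by planning over a cognitive map. `gridnav`
implements the computational version of that distinction for a grid-world
wayfinding task and is aimed at behavioural/cognitive-neuroscience
researchers who want to quantify navigation strategy from choice logs:

* a **task environment**: a 5×5 grid of rooms connected by doors, no
  backtracking through the door just entered, three ordered reward rooms,
  and three phases — *encoding* (8 trials, fixed start, three rewards in
  order), *retrieval* (15 single-reward trials, same start) and *search*
  (single-reward trials from varying starts);
* three **choice models** evaluated on the same state–action space
  (25 rooms × 4 absolute directions):
  - model-free **SARSA(λ)** — on-policy learning with replacing eligibility
    traces, `δ_i = R + Q_MF(s_{i+1}, a_{i+1}) − Q_MF(s_i, a_i)`, one
    independent table per reward context;
  - **model-based planning** — the fixed point of
    `Q_MB(s,a) = R(s')` if `s'` is the reward, else
    `(1−γ)·max_{a'} Q_MB(s',a')` with γ = 0.1, solved by synchronous value
    iteration (converges within 25 sweeps on the default maze);
  - the **hybrid** `Q = (1−ω)·Q_MF + ω·Q_MB`, with softmax choice
    `p(a) ∝ exp(β·Q)`; ω ∈ [0,1] measures how model-based a subject is;
* three **navigation indices** per phase:
  `I_PATH = n_shortest_trial / n_total_trial`,
  `I_STEPS = (n_max_steps − n_obs_steps) / (n_max_steps − n_shortest_steps)`,
  `I_ROUTE = n_route_trial / (n_route_trial + n_shortest_trial)` with a
  60% transition-overlap rule against the route established in encoding;
* **model fitting** (MAP with weakly informative priors, multi-start
  L-BFGS-B, per subject × phase), model comparison by AIC/BIC, and
  cohort-level correlation of fitted ω with the indices plus
  parameter-recovery reporting on synthetic cohorts.

Because no human data ship with the package, a seeded synthetic-cohort
generator produces subjects from the hybrid model at the study's trial
counts, so every stage is testable end to end.

## Worked example

```python
from gridnav import (FitConfig, default_maze, fit_cohort, omega_index_report,
                     omega_summary, recovery_report, simulate_cohort)
from gridnav.indices import compute_indices

maze = default_maze()
logs, truth = simulate_cohort(maze, n_subjects=12, seed=3,
                              param_sampler={"beta": (2.0, 8.0)})
fits = fit_cohort(logs, "hybrid", maze, FitConfig(n_restarts=10, seed=3))
print(recovery_report(truth, fits).round(3))
```

prints

```
parameter     r   bias  rmse  n
    alpha 0.456  0.104 0.223 12
     beta 0.560  0.798 1.810 12
      lam 0.610 -0.023 0.189 12
    omega 0.870  0.075 0.161 12
```

i.e. the hybrid weight ω — the quantity of scientific interest — is
recovered with r ≈ 0.87 from 12 subjects at study-scale trial counts, while
the learning rate α and trace decay λ are only weakly identified.
`omega_index_report(omega_summary(fits), compute_indices(logs, maze)[1])`
then correlates fitted ω with each navigation index (see
`examples/05_full_pipeline.py`, and `docs/methods.md` for why the
ω–optimality coupling is weak in this generative model).

The `examples/` directory holds one short script per capability (maze and
planning values, cohort simulation, indices, model fitting and comparison,
full pipeline); each prints its numbers with a line on what they mean. A
thin CLI mirrors the pipeline stages:

```bash
gridnav simulate --n-subjects 27 --seed 1 --out-log log.tsv --out-truth truth.tsv
gridnav fit log.tsv --model hybrid --out fits.tsv
gridnav indices log.tsv --out indices.tsv
gridnav report --fits fits.tsv --indices indices.tsv --truth truth.tsv --out report.tsv
```

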