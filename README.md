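# mazestrat

Stochastic characterisation of navigation strategies in an automated
Barnes-maze variant: a circular arena whose periphery carries 24 evenly
spaced entry chambers ("vestibules"), one of which hides the goal. A mouse
released at a random peripheral start position visits a sequence of
vestibules before finding the goal; the pattern of those visits is what this
package models.

`mazestrat` is aimed at behavioural neuroscientists and computational
ethologists who want to go beyond one-label-per-trial strategy scoring: it
segments trajectories into vestibule sequences, summarises them with four
normalised distributions, and explains them with generative stochastic
processes whose mixing weights are estimated by simulation.

## The models

Vestibules are indexed 0–23 in a goal-centred frame (goal = 0, indices
increasing clockwise). Three stochastic processes draw the next vestibule
V\_{i+1} from the current one V\_i:

* **random** — uniform over the 23 other vestibules;
* **spatial** — P(v) ∝ exp(−d(v, goal)/τ) with d the door-distance and
  τ = 2, redrawn if v = V\_i (goal-directed, allocentric search);
* **serial** — V\_{i+1} = V\_i + S with S = round(c + σ·z), z ~ N(0, 1);
  clockwise steps (c = 1.2, σ = 1.2) are drawn with probability 0.8,
  counterclockwise ones (c = −2, σ = 1.5) with probability 0.2
  (consecutive-door search).

Two generative models combine them:

* **Mixture model with persistence N** — at the start of a trial and after
  every N segments a strategy is drawn from (P\_random, P\_serial,
  P\_spatial); the selected process generates the next N segments. Fitted
  by exhaustive grid search: every probability triple on a 2 %-step simplex
  grid is simulated on the experimental start schedule, summarised, and
  scored by the mean squared error against the observed distributions
  (trial length, vestibule visits, segment size, serial bout length);
  surfaces are averaged over 10 repetitions. N is estimated by repeating
  the search for N = 1..15.
* **Markov chain model** — four strategies (random, serial clockwise,
  serial counterclockwise, spatial) form a Markov chain over segments,
  parameterised by a 5×4 row-stochastic matrix (initial probabilities +
  transition rows) and fitted by a genetic algorithm (population 500,
  elitism 250, alternating mutation and row crossover, 500 generations)
  against position-resolved distributions of the first 10 segments plus
  trial-length and bout-length distributions.

A synthetic-experiment generator reproduces the study structure (19 mice,
10 trials/day, 19 days, starts ≥ 2 door-intervals from the goal, the same
per-day start sequence for every mouse), so every estimator can be
validated by parameter recovery on ground-truth-labelled data.

## Worked example

```python
import numpy as np
from mazestrat import (ExperimentPlan, GridFitConfig, MixtureModel,
                       MixtureParams, generate_dataset, make_start_schedule)

# a synthetic "day 1": 19 mice x 10 trials, mostly-random searching
plan = ExperimentPlan(n_mice=19, days=1, trials_per_day=10,
                      params=MixtureParams(58.2, 28.4, 13.4, n_persist=6))
rng = np.random.default_rng(7)
data = generate_dataset(plan, rng, schedule=make_start_schedule(plan, rng))

res = MixtureModel(data).fit(n_persist=6,
                             grid=GridFitConfig(increment=4, repetitions=10),
                             seed=11)
print(res.summary())
```

prints

```
Mixture-of-strategies fit (exhaustive grid search)
======================================================
trials in target:             190
grid increment:                 4 %
repetitions averaged:          10
------------------------------------------------------
strategy      estimate (%)     rep. SD
random                56.0        5.48
serial                28.0        6.53
spatial               16.0        5.48
------------------------------------------------------
persistence N:                  6
minimal averaged MSE:       1.078e-04
```

i.e. the generating mix (58.2 / 28.4 / 13.4) is recovered to within a few
percentage points from 190 trials; the repetition SD column is the spread
of the per-repetition argmins, a measure of the estimator's sampling
noise at this data size. `MarkovStrategyModel(data).fit(...)` returns the
GA fit of the 5×4 strategy-transition matrix with per-repetition
convergence diagnostics, and `classify_dataset(data)` gives the classical
one-label-per-trial baseline for comparison.

A `mazestrat` command-line tool exposes the same pipeline
(`synth`, `simulate`, `summarize`, `fit-mixture`, `fit-markov`,
`classify`); see `mazestrat --help`.

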