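# Methods

## Setting and conventions

The arena is a circular floor (95 cm across) ringed by 24 vestibules behind
doors 15° apart. All analyses use a goal-centred frame: vestibule indices
run 0–23 with the goal at 0, and indices increase **clockwise**, so a
positive segment of k door-intervals is k doors clockwise — matching the
convention that positive segment sizes denote clockwise travel. Whether
physical labels increased clockwise or counterclockwise is not observable
from sequence data; the choice is internal and self-consistent. The
antipodal step (12 doors, where both directions are equally short) is
signed +12 when only sequences are available; the xy segmenter could in
principle use the observed travel direction instead.

A *trial* is a start vestibule plus the ordered vestibules visited until
the goal; its *segments* are signed door-steps between consecutive
vestibules (±1..±12; 0 is impossible because no process and no valid
recording revisits the current vestibule consecutively). A *serial bout*
is a maximal run of same-direction one-door segments; runs of +1 and runs
of −1 are distinct bouts, matching the single-direction semantics of the
serial process. Bouts have length ≥ 1 (an isolated one-door segment is a
bout of one).

## Stochastic strategy processes

* **Random**: uniform over the 23 vestibules other than the current one.
  The plain description of this process is a uniform draw over all 24;
  we exclude the current vestibule (by exact renormalisation, equivalent
  to redrawing) because a same-vestibule "visit" would create a
  zero-size segment, which the segment algebra excludes. With this
  convention a pure-random trial length is geometric with success
  probability 1/23 (mean 23), which the tests verify.
* **Spatial**: P(v) ∝ exp(−d(v, goal)/τ), τ = 2 door-intervals, the
  current vestibule excluded and the remainder renormalised. We sample the
  categorical distribution exactly rather than through an integer-rounded
  cumulative-sum lookup; the latter is the quantised limit of the former.
* **Serial**: step S = round(c_dir + σ_dir·z) with z standard normal;
  clockwise c = +1.2, σ = 1.2; counterclockwise c = −2, σ = 1.5. In the
  unified (mixture-model) form the sign is drawn first, positive with
  p_cw = 0.8. S is redrawn until it is nonzero and its sign matches the
  drawn (or fixed) direction — the continuous-to-integer conversion and
  the treatment of sign-contradicting draws are our choices, made so that
  a "clockwise" step can never move counterclockwise. The offsets set the
  two peaks of the segment-size distribution, the σ's their widths, and
  p_cw their height ratio.

Every process is exposed both as a scalar per-step draw (the reference
implementation) and as a vectorised batch simulator that advances all
trials of a dataset in lock-step. The batch path is what makes the
exhaustive grid search and the genetic algorithm affordable on one CPU;
tests check that batch and scalar draws agree in distribution (chi-square
against closed-form oracles) and that batch trial-length distributions
match the scalar simulator (two-sample KS).

## Summary distributions and the objective

Four pooled distributions summarise a trial set: trial length (1..30,
overflow pooled into the top bin), vestibule visits (24 bins), segment
size (−12..−1, +1..+12), and serial bout length (1..15, overflow pooled).
The caps are configurable; pooling conserves mass. The mean squared error
between two summary sets is the mean of squared bin-wise differences over
the concatenation of all component vectors — equal bin weight, the
simplest reading of an unweighted "mean square error of the fits", and
configurable through the objective component list.

The Markov-chain objective replaces the pooled segment-size and vestibule
distributions by their position-resolved versions over the first 10
segments of each trial (10 rows each), plus the pooled trial-length and
bout-length distributions. Rows beyond a trial's length contribute
nothing; unpopulated rows are zero vectors.

## Mixture model and grid search

Generation alternates a strategy draw (uniform x on [0, 100): random if
x < P_random, serial if x > P_random + P_spatial, else spatial) with N
segments from the selected process, stopping at the goal. The fit
simulates every triple on the increment-2 simplex grid (1,326 points)
using the experimental start schedule, repeats everything 10 times, and
averages the **error surfaces** before taking the argmin; averaging the
per-repetition argmins instead is available (`average="argmin"`) but the
surface average is the default because it yields a smoother, deterministic
landscape. Exact ties on the surface (possible only in degenerate
settings) resolve toward larger P_spatial, then larger P_serial. The
N-scan repeats the whole search for N = 1..15 and keeps the N with the
lowest averaged minimal error, ties toward smaller N. Per-day fits reuse
that day's start schedule.

Self-consistency at experiment scale (190 trials, 10 repetitions): the
recovered triple lies within a few percentage points of the generating
one, with a per-repetition argmin SD of ~5 points; recovery error shrinks
with schedule size. The N-scan on ~600 generated trials shows a clear
minimum at the generating N.

## Markov chain model and genetic algorithm

Strategies (random, serial CW, serial CCW, spatial — this row order is
fixed throughout) are redrawn before every segment: from the initial row
at the first segment, then from the transition row of the previous
strategy. The GA represents each individual as a 5×4 matrix; rows are
initialised from a flat Dirichlet (the original initialisation is stated
only as "random"). Each generation evaluates all individuals by
simulating the schedule once and scoring the objective above, keeps the
best half, and refills the other half by mutation (uniform noise on
(−0.1, 0.1) added elementwise, negatives clamped, rows renormalised;
all-zero rows fall back to uniform) on even generations and row-wise
crossover of random elite pairs on odd ones. Evaluation uses fresh
simulation seeds each generation by default (reduces overfitting to one
noise draw); a frozen-seed mode re-uses one seed so that elitism makes
the best fitness provably non-increasing, which the tests exercise. A
run's answer is the renormalised element-wise mean of the final elite;
across repetitions the result with the lowest final error is reported
best, with the per-run matrices and their element-wise SD kept as a
convergence diagnostic.

### Identifiability of the transition matrix

The GA objective contains only position-resolved *marginal* distributions
(plus trial-length and bout-length), not segment-to-segment joint
statistics. The transition matrix therefore enters the objective almost
exclusively through the occupancy trajectory p_k = p_1·T^(k−1) and
through run-length statistics visible in the bout distribution. Directions
of parameter space that leave these nearly unchanged — notably how
probability mass leaving the *random* state is shared among destinations —
are weakly constrained: at a 1,900-trial target the objective change from
a 0.25 perturbation of such a row (~1.2e−5) is smaller than the sampling
noise floor of the target itself (~7e−5). In recovery experiments the
initial-probability row and strongly self-persistent transition rows are
recovered to a few hundredths, while weakly constrained transition
entries drift (toward uniform, the stationary point of the
mutation-clamp-renormalise operator) by up to a few tenths, consistently
across GA repetitions. This is a property of the estimator's objective at
these sample sizes, not of the optimiser: the best GA individuals reach
error levels at or below the target's own noise floor, and the drift
pattern is reproduced across independent GA runs and across differently
structured generating matrices. The test suite therefore contains two
recovery checks at scaled settings: the identifiable initial-strategy row
is recovered within ±0.1 per entry, while the uniform ±0.1 bound over the
full 5×4 matrix is kept as a strict check that fails at these scales —
an expected failure that quantifies the limitation rather than a defect
of the fitting machinery. Users interpreting fitted transition rows
should lean on the cross-repetition spread diagnostics.

## Trajectory segmentation

Visits are detected on the radial coordinate: a visit opens when the
path reaches 47.5 cm from the centre and closes at the next inward
crossing; identity is the nearest 15°-sector centre by angle at entry. A
single threshold with no debouncing window is used; immediate re-entries
into the same vestibule are collapsed when converting events to a visit
sequence, since they carry no segment. Path length is the integrated
per-step Euclidean displacement.

## Synthetic data

The generator is the package's test bed, not a behavioural model: paths
between vestibules are arcs at 0.9× the visit radius with radial pokes
3 cm beyond the threshold, resampled at 25 samples/s and 25 cm/s with
0.5 cm Gaussian jitter — parameters chosen so that threshold crossings
are unambiguous (≥ 6 jitter SDs of margin), which the exact round-trip
test (segmentation must reproduce the generating sequence) relies on.
Realistic rodent kinematics (variable speed, wall-following curvature,
grazing near-crossings) are deliberately absent, so passing round-trip
tests validate the segmentation logic, not its robustness to tracking
noise in real videos. Sequence-level realism (trial lengths, visit
distributions, bout structure) comes from the generative processes
themselves; sex labels (10 male / 9 female by default) exist so group-wise
pipeline reruns can be exercised, with optionally different generating
parameters per group.

## Problem sizes and numerical choices

Recovery experiments run at the study's structure: 190 trials for per-day
probability recovery, ~600 trials for the N-scan (coarser increment-10
probability grid), 1,900 trials for the Markov-chain target, and a scaled
GA (population 100, 100 generations) for recovery experiments — sizes at
which each check completes in minutes on a single core while leaving the
estimators' sampling behaviour visible. The full-scale GA settings
(population 500, 500 generations, 10 repetitions) remain the defaults of
`GAConfig`. All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning, so every fit, simulation and CSV is
bit-reproducible; per-(repetition, grid-point) child seeds make grid
surfaces independent of evaluation order. The step guard
(`max_steps_per_trial`, default 1000) bounds pathological trials; a
truncation rate above 1 % in the synthetic generator raises rather than
silently biasing distributions. Probability vectors are validated to
1e−6; summary normalisation tolerates empty components (zero vectors) so
per-position rows beyond the longest trial are well-defined.

## Known limitations

* Strategy inference is generative-parameter fitting only; no per-segment
  posterior decoding of which strategy produced an observed segment.
* The mixture estimator is simulation-based MSE minimisation, so its
  precision is bounded by simulation noise (mitigated by repetition
  averaging) and grid resolution.
* Full transition-matrix identifiability is limited by the marginal
  objective (see above); conclusions about weakly constrained entries
  should rely on the cross-repetition spread diagnostics.
* The xy segmenter assumes clean, arena-centred, goal-aligned coordinates
  at a uniform sample rate; video tracking artefacts are out of scope.
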