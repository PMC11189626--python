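"""Four-strategy Markov chain model and its genetic-algorithm fit.

Strategies (random, serial clockwise, serial counterclockwise, spatial) are
the states of a Markov chain; a strategy is redrawn before *every* segment —
from an initial probability vector at the first segment, and from the
transition row of the previous segment's strategy afterwards.  The full
parameter set is a 5 x 4 row-stochastic matrix: row 0 the initial
probabilities, rows 1-4 the transitions out of each strategy.

Fitting is by a genetic algorithm over 5 x 4 matrices: in every generation
each individual is simulated on the experimental start schedule and scored
by the MSE between simulated and target distributions (segment-size and
vestibule distributions resolved over the first 10 segment positions, plus
trial-length and serial-bout distributions); the best half survives and the
other half is refilled by mutation and row-crossover of survivors in
alternating generations.  The answer is the renormalised element-wise mean
of the final elite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import DEFAULT_MAZE, Dataset, MazeConfig, Trial
from .simulate import SequenceBatch, simulate_markov_batch
from .strategies import (
    MARKOV_STRATEGIES,
    StrategyParams,
    draw_random_step,
    draw_serial_step,
    draw_spatial_step,
)
from .summaries import (
    DEFAULT_K,
    PerIndexSummary,
    SummarySet,
    mse,
    summarize,
    summarize_per_index,
)

__all__ = [
    "MarkovParams",
    "GAConfig",
    "GAResult",
    "MarkovStrategyModel",
    "simulate_markov_trial",
    "simulate_markov_dataset",
    "normalize_rows",
    "mutate",
    "crossover",
    "markov_objective",
    "ga_fit",
]


@dataclass(frozen=True)
class MarkovParams:
    """Initial strategy probabilities and strategy transition matrix.

    Row order everywhere is (random, serial_cw, serial_ccw, spatial).
    """

    initial: tuple[float, ...]
    transitions: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (5, 4):
            raise ValueError("expected 4 initial probabilities and a 4x4 "
                             "transition matrix")
        if (m < -1e-9).any() or np.abs(m.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("rows must be >= 0 and sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        """The stacked 5 x 4 matrix (row 0 = initial, rows 1-4 = transitions)."""
        return np.vstack([np.asarray(self.initial, dtype=float),
                          np.asarray(self.transitions, dtype=float)])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "MarkovParams":
        m = np.asarray(m, dtype=float)
        return cls(tuple(m[0]), tuple(tuple(row) for row in m[1:]))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the full-scale fit (population 500, 500 generations,
    elite 250, mutation noise uniform on (-0.1, 0.1), 10 repetitions);
    recovery tests use scaled-down values.
    """

    population: int = 500
    generations: int = 500
    elite: int = 250
    mutation_half_range: float = 0.1
    repetitions: int = 10
    k_segments: int = DEFAULT_K
    frozen_eval: bool = False

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 < self.elite < self.population:
            raise ValueError("elite must be in 1..population-1")
        if self.mutation_half_range <= 0:
            raise ValueError("mutation_half_range must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class GAResult:
    """Outcome of one or more GA repetitions.

    ``best_matrix`` is the renormalised average of the final elite of the
    repetition with the lowest final error; ``per_run_matrices`` keeps every
    repetition's answer for convergence diagnostics.
    """

    best_matrix: MarkovParams
    error_traces: np.ndarray            # (repetitions, generations)
    per_run_matrices: list[MarkovParams]

    @property
    def error_trace(self) -> np.ndarray:
        best = int(np.argmin(self.error_traces[:, -1]))
        return self.error_traces[best]

    def matrix_spread(self) -> np.ndarray:
        """Element-wise SD of the per-repetition matrices."""
        stack = np.stack([p.matrix for p in self.per_run_matrices])
        return stack.std(axis=0, ddof=1) if stack.shape[0] > 1 \
            else np.zeros_like(stack[0])


def simulate_markov_trial(params: MarkovParams, start: int,
                          rng: np.random.Generator,
                          config: MazeConfig = DEFAULT_MAZE,
                          strategy_params: StrategyParams = StrategyParams(),
                          *, mouse_id: str = "sim", day: int = 1,
                          trial: int = 1) -> Trial:
    """Scalar reference simulation of a single Markov-chain trial."""
    if not 0 <= start < config.n_vestibules:
        raise ValueError("start out of range")
    initial = np.asarray(params.initial, dtype=float)
    trans = np.asarray(params.transitions, dtype=float)
    visits: list[int] = []
    labels: list[str] = []
    current = start
    truncated = False
    state = -1
    if start != config.goal_index:
        for _ in range(strategy_params.max_steps_per_trial):
            p = initial if state < 0 else trans[state]
            state = int(rng.choice(4, p=p / p.sum()))
            name = MARKOV_STRATEGIES[state]
            if name == "random":
                current = draw_random_step(current, rng, config)
            elif name == "spatial":
                current = draw_spatial_step(current, rng, config,
                                            strategy_params.spatial)
            else:
                current, _s = draw_serial_step(
                    current, rng, config, strategy_params.serial,
                    "cw" if name == "serial_cw" else "ccw")
            visits.append(current)
            labels.append(name)
            if current == config.goal_index:
                break
        else:
            truncated = True
    return Trial(mouse_id, day, trial, start, tuple(visits),
                 strategy_labels=tuple(labels), truncated=truncated)


def simulate_markov_dataset(params: MarkovParams,
                            schedule: pd.DataFrame,
                            rng: np.random.Generator,
                            config: MazeConfig = DEFAULT_MAZE,
                            strategy_params: StrategyParams = StrategyParams(),
                            ) -> Dataset:
    """Simulate one Markov-chain trial per schedule row."""
    if schedule.empty:
        raise ValueError("empty schedule")
    m = params.matrix
    batch = simulate_markov_batch(m[0], m[1:], schedule["start"].to_numpy(),
                                  rng, config, strategy_params)
    trials = batch.to_trials(mouse_ids=schedule["mouse_id"].to_numpy(),
                             days=schedule["day"].to_numpy(),
                             trial_nums=schedule["trial"].to_numpy())
    return Dataset(trials, {"model": "markov"})


def normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Clamp negatives to zero and rescale each row to sum to 1.

    A row that is all zero after clamping falls back to the uniform row.
    """
    m = np.maximum(np.asarray(matrix, dtype=float), 0.0)
    sums = m.sum(axis=-1, keepdims=True)
    uniform = np.full_like(m, 1.0 / m.shape[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, m / np.where(sums > 0, sums, 1.0), uniform)
    return out


def mutate(individual: np.ndarray, rng: np.random.Generator,
           cfg: GAConfig = GAConfig()) -> np.ndarray:
    """Add independent uniform(-h, h) noise to every element, renormalise."""
    h = cfg.mutation_half_range
    return normalize_rows(individual + rng.uniform(-h, h, individual.shape))


def crossover(a: np.ndarray, b: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Each row taken from ``a`` or ``b`` with a fair coin."""
    if a.shape != b.shape:
        raise ValueError("parents must have matching shapes")
    pick = rng.integers(0, 2, a.shape[0]).astype(bool)
    return np.where(pick[:, None], a, b)


def markov_objective(data: Dataset | SequenceBatch,
                     config: MazeConfig = DEFAULT_MAZE,
                     k: int = DEFAULT_K) -> np.ndarray:
    """Objective vector of the GA fit: per-position segment-size and
    vestibule distributions (first ``k`` segments) plus the pooled
    trial-length and serial-bout distributions."""
    per_index = summarize_per_index(data, config, k=k)
    pooled = summarize(data, config)
    return np.concatenate([per_index.as_vector(),
                           pooled.trial_length, pooled.serial_bout])


def _ga_run(target_vec: np.ndarray, starts: np.ndarray, cfg: GAConfig,
            ss: np.random.SeedSequence, config: MazeConfig,
            strategy_params: StrategyParams
            ) -> tuple[np.ndarray, np.ndarray]:
    init_ss, eval_ss, op_ss = ss.spawn(3)
    rng = np.random.default_rng(init_ss)
    op_rng = np.random.default_rng(op_ss)
    pop = rng.dirichlet(np.ones(4), size=(cfg.population, 5))
    eval_children = ([eval_ss] * cfg.generations if cfg.frozen_eval
                     else eval_ss.spawn(cfg.generations))

    def fitness(ind: np.ndarray, gen_seed) -> float:
        r = np.random.default_rng(gen_seed)
        batch = simulate_markov_batch(ind[0], ind[1:], starts, r,
                                      config, strategy_params)
        sim = markov_objective(batch, config, k=cfg.k_segments)
        return mse(target_vec, sim)

    trace = np.empty(cfg.generations)
    elite = None
    for gen in range(cfg.generations):
        gen_seed = eval_children[gen]
        fits = np.array([fitness(ind, gen_seed) for ind in pop])
        order = np.argsort(fits, kind="stable")
        elite = pop[order[: cfg.elite]]
        trace[gen] = fits[order[0]]
        if gen == cfg.generations - 1:
            break
        n_new = cfg.population - cfg.elite
        if gen % 2 == 0:   # mutation generation
            parents = elite[op_rng.integers(0, cfg.elite, n_new)]
            children = normalize_rows(
                parents + op_rng.uniform(-cfg.mutation_half_range,
                                         cfg.mutation_half_range,
                                         parents.shape))
        else:              # crossover (mixing) generation
            ia = op_rng.integers(0, cfg.elite, n_new)
            ib = op_rng.integers(0, cfg.elite, n_new)
            pick = op_rng.integers(0, 2, (n_new, 5, 1)).astype(bool)
            children = np.where(pick, elite[ia], elite[ib])
        pop = np.concatenate([elite, children])
    best = normalize_rows(elite.mean(axis=0))
    return best, trace


def ga_fit(target: np.ndarray | Dataset, schedule: pd.DataFrame,
           cfg: GAConfig = GAConfig(),
           seed: int | np.random.SeedSequence = 0,
           config: MazeConfig = DEFAULT_MAZE,
           strategy_params: StrategyParams = StrategyParams()) -> GAResult:
    """Run ``cfg.repetitions`` independent GA repetitions against ``target``.

    ``target`` may be a Dataset (the objective vector is computed from it)
    or a precomputed objective vector from :func:`markov_objective`.
    """
    if isinstance(target, Dataset):
        target = markov_objective(target, config, k=cfg.k_segments)
    if schedule.empty:
        raise ValueError("empty schedule")
    starts = schedule["start"].to_numpy()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    runs = [_ga_run(target, starts, cfg, child, config, strategy_params)
            for child in ss.spawn(cfg.repetitions)]
    matrices = [MarkovParams.from_matrix(m) for m, _ in runs]
    traces = np.stack([t for _, t in runs])
    best = matrices[int(np.argmin(traces[:, -1]))]
    return GAResult(best, traces, matrices)


class MarkovStrategyModel:
    """Markov-chain strategy model bound to an observed trial set.

    The target distributions are computed from ``data`` (typically trials
    pooled over the post-learning days); the GA simulates candidate matrices
    on the same start schedule.
    """

    def __init__(self, data: Dataset,
                 schedule: pd.DataFrame | None = None,
                 config: MazeConfig = DEFAULT_MAZE,
                 strategy_params: StrategyParams = StrategyParams()):
        self.data = data
        self.config = config
        self.strategy_params = strategy_params
        if schedule is None:
            schedule = pd.DataFrame(
                [(t.mouse_id, t.day, t.trial, t.start) for t in data],
                columns=["mouse_id", "day", "trial", "start"])
        if schedule.empty:
            raise ValueError("empty schedule")
        self.schedule = schedule

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs
                       ) -> "MarkovStrategyModel":
        return cls(Dataset.from_dataframe(df), **kwargs)

    def fit(self, cfg: GAConfig = GAConfig(),
            seed: int | np.random.SeedSequence = 0) -> "MarkovResults":
        target = markov_objective(self.data, self.config, k=cfg.k_segments)
        res = ga_fit(target, self.schedule, cfg, seed, self.config,
                     self.strategy_params)
        return MarkovResults(self, res, cfg, seed)


class MarkovResults:
    """Fitted Markov-chain model: matrix estimate, run spread, error traces."""

    def __init__(self, model: MarkovStrategyModel, fit: GAResult,
                 cfg: GAConfig, seed):
        self.model = model
        self._fit = fit
        self.cfg = cfg
        self.seed = seed

    @property
    def params(self) -> MarkovParams:
        return self._fit.best_matrix

    @property
    def error_trace(self) -> np.ndarray:
        return self._fit.error_trace

    @property
    def error_traces(self) -> np.ndarray:
        return self._fit.error_traces

    @property
    def per_run_matrices(self) -> list[MarkovParams]:
        return self._fit.per_run_matrices

    def matrix_spread(self) -> np.ndarray:
        return self._fit.matrix_spread()

    def simulate(self, rng: np.random.Generator,
                 schedule: pd.DataFrame | None = None) -> Dataset:
        return simulate_markov_dataset(
            self.params, schedule if schedule is not None else
            self.model.schedule, rng, self.model.config,
            self.model.strategy_params)

    def summary(self) -> str:
        m = self.params.matrix
        sd = self.matrix_spread()
        names = list(MARKOV_STRATEGIES)
        lines = [
            "Markov-chain strategy fit (genetic algorithm)",
            "=" * 62,
            f"population {self.cfg.population}, generations "
            f"{self.cfg.generations}, elite {self.cfg.elite}, "
            f"repetitions {self.cfg.repetitions}",
            f"final best MSE: {self.error_trace[-1]:.3e}",
            "-" * 62,
            "from / to   " + "".join(f"{n:>12}" for n in names),
        ]
        row_names = ["(initial)"] + names
        for rn, row, srow in zip(row_names, m, sd):
            cells = "".join(f"{v:>7.2f}±{s:<4.2f}" for v, s in zip(row, srow))
            lines.append(f"{rn:<12}{cells}")
        return "\n".join(lines)

    def plot_error_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tr in self.error_traces:
            ax.plot(tr, alpha=0.6)
        ax.set_xlabel("generation")
        ax.set_ylabel("best MSE")
        return ax
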