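"""Mixture of the three strategy processes with persistence N, and its fit.

The generative model: at the start of a trial, and again after every block
of ``N`` segments, a strategy is drawn according to (P_random, P_serial,
P_spatial); the selected process then produces the next ``N`` vestibules
(fewer if the goal is reached first).  ``N`` — the strategy persistence — is
the number of consecutive segments generated under one strategy.

The estimator is pure simulation-based: for every probability triple on a
simplex grid (step ``increment`` percent) the model is simulated on the
experimental start schedule, summarised, and compared to the target's
summary distributions by mean squared error; surfaces are averaged over
``repetitions`` independent simulations before the argmin is taken.  The
persistence is estimated by repeating the whole grid search for each N in
``n_range`` and selecting the N with the lowest averaged minimal error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import DEFAULT_MAZE, Dataset, MazeConfig, Trial
from .simulate import simulate_mixture_batch
from .strategies import (
    MIXTURE_STRATEGIES,
    StrategyParams,
    draw_random_step,
    draw_serial_step,
    draw_spatial_step,
)
from .summaries import SummarySet, mse, summarize

__all__ = [
    "MixtureParams",
    "GridFitConfig",
    "MixtureFitResult",
    "MixtureModel",
    "simulate_mixture_trial",
    "simulate_mixture_dataset",
    "enumerate_simplex_grid",
    "fit_mixture_grid",
    "scan_n",
]


@dataclass(frozen=True)
class MixtureParams:
    """Strategy probabilities (percent, summing to 100) and persistence N."""

    p_random: float
    p_serial: float
    p_spatial: float
    n_persist: int = 6

    def __post_init__(self) -> None:
        if min(self.p_random, self.p_serial, self.p_spatial) < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_random + self.p_serial + self.p_spatial - 100.0) > 1e-6:
            raise ValueError("probabilities must sum to 100")
        if self.n_persist < 1:
            raise ValueError("n_persist must be >= 1")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.p_random, self.p_serial, self.p_spatial)


@dataclass(frozen=True)
class GridFitConfig:
    """Grid-search settings for the mixture fit."""

    increment: int = 2
    n_range: tuple[int, ...] = tuple(range(1, 16))
    repetitions: int = 10
    objective: tuple[str, ...] = SummarySet.COMPONENTS
    average: str = "surface"   # or "argmin"

    def __post_init__(self) -> None:
        if self.increment <= 0 or 100 % self.increment != 0:
            raise ValueError("increment must divide 100")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.n_range:
            raise ValueError("n_range must be non-empty")
        if self.average not in ("surface", "argmin"):
            raise ValueError("average must be 'surface' or 'argmin'")


def enumerate_simplex_grid(increment: int) -> np.ndarray:
    """All (P_random, P_serial, P_spatial) >= 0 summing to 100 on the grid."""
    if increment <= 0 or 100 % increment != 0:
        raise ValueError("increment must divide 100")
    pts = []
    for a in range(0, 101, increment):
        for b in range(0, 101 - a, increment):
            pts.append((a, b, 100 - a - b))
    return np.array(pts, dtype=float)


def simulate_mixture_trial(params: MixtureParams, start: int,
                           rng: np.random.Generator,
                           config: MazeConfig = DEFAULT_MAZE,
                           strategy_params: StrategyParams = StrategyParams(),
                           *, mouse_id: str = "sim", day: int = 1,
                           trial: int = 1) -> Trial:
    """Scalar reference simulation of a single mixture-model trial."""
    if not 0 <= start < config.n_vestibules:
        raise ValueError("start out of range")
    visits: list[int] = []
    labels: list[str] = []
    current = start
    truncated = False
    rem = 0
    strat = "random"
    if start != config.goal_index:
        for _ in range(strategy_params.max_steps_per_trial):
            if rem == 0:
                x = rng.uniform(0.0, 100.0)
                if x < params.p_random:
                    strat = "random"
                elif x > params.p_random + params.p_spatial:
                    strat = "serial"
                else:
                    strat = "spatial"
                rem = params.n_persist
            if strat == "random":
                current = draw_random_step(current, rng, config)
            elif strat == "serial":
                current, _s = draw_serial_step(
                    current, rng, config, strategy_params.serial, "unified")
            else:
                current = draw_spatial_step(
                    current, rng, config, strategy_params.spatial)
            rem -= 1
            visits.append(current)
            labels.append(strat)
            if current == config.goal_index:
                break
        else:
            truncated = True
    return Trial(mouse_id, day, trial, start, tuple(visits),
                 strategy_labels=tuple(labels), truncated=truncated)


def simulate_mixture_dataset(params: MixtureParams,
                             schedule: pd.DataFrame,
                             rng: np.random.Generator,
                             config: MazeConfig = DEFAULT_MAZE,
                             strategy_params: StrategyParams = StrategyParams(),
                             ) -> Dataset:
    """Simulate one trial per schedule row (columns mouse_id, day, trial, start)."""
    if schedule.empty:
        raise ValueError("empty schedule")
    batch = simulate_mixture_batch(params.probs, params.n_persist,
                                   schedule["start"].to_numpy(), rng,
                                   config, strategy_params)
    trials = batch.to_trials(mouse_ids=schedule["mouse_id"].to_numpy(),
                             days=schedule["day"].to_numpy(),
                             trial_nums=schedule["trial"].to_numpy())
    return Dataset(trials, {"model": "mixture",
                            "params": {"p_random": params.p_random,
                                       "p_serial": params.p_serial,
                                       "p_spatial": params.p_spatial,
                                       "n_persist": params.n_persist}})


@dataclass
class MixtureFitResult:
    """Outcome of one grid search at fixed N (or of an N-scan)."""

    best: MixtureParams
    error_surface: pd.DataFrame          # columns p_random, p_serial, p_spatial, mse
    repetitions_used: int
    per_rep_best: pd.DataFrame | None = None   # argmin triple per repetition
    error_by_n: pd.Series | None = None        # minimal averaged mse per N

    @property
    def min_mse(self) -> float:
        return float(self.error_surface["mse"].min())


def _surface_argmin(points: np.ndarray, errors: np.ndarray) -> int:
    """Index of the minimal error; ties resolve toward larger P_spatial,
    then larger P_serial (deterministic)."""
    emin = errors.min()
    cand = np.flatnonzero(errors == emin)
    order = np.lexsort((points[cand, 1], points[cand, 2]))
    return int(cand[order[-1]])


def fit_mixture_grid(target: SummarySet,
                     schedule: pd.DataFrame,
                     grid: GridFitConfig = GridFitConfig(),
                     n_persist: int = 6,
                     seed: int | np.random.SeedSequence = 0,
                     config: MazeConfig = DEFAULT_MAZE,
                     strategy_params: StrategyParams = StrategyParams(),
                     ) -> MixtureFitResult:
    """Exhaustive simplex-grid search for the strategy probabilities.

    For every grid triple, ``grid.repetitions`` datasets are simulated on
    ``schedule`` and summarised; their MSEs against ``target`` are averaged
    and the argmin of the averaged surface is returned (``grid.average ==
    'argmin'`` instead averages the per-repetition argmin triples).
    """
    points = enumerate_simplex_grid(grid.increment)
    starts = schedule["start"].to_numpy()
    target_vec = target.as_vector(grid.objective)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(grid.repetitions * len(points))
    errs = np.empty((len(points), grid.repetitions))
    for r in range(grid.repetitions):
        for i, (pr, pse, psp) in enumerate(points):
            rng = np.random.default_rng(children[r * len(points) + i])
            batch = simulate_mixture_batch((pr, pse, psp), n_persist, starts,
                                           rng, config, strategy_params)
            sim = summarize(batch, config, l_max=target.l_max,
                            b_max=target.b_max)
            errs[i, r] = mse(target_vec, sim.as_vector(grid.objective))
    mean_err = errs.mean(axis=1)
    per_rep = pd.DataFrame(
        [points[_surface_argmin(points, errs[:, r])]
         for r in range(grid.repetitions)],
        columns=["p_random", "p_serial", "p_spatial"],
    )
    if grid.average == "surface":
        best_triple = points[_surface_argmin(points, mean_err)]
    else:
        best_triple = per_rep.mean().to_numpy()
        s = best_triple.sum()
        best_triple = best_triple * (100.0 / s)
    surface = pd.DataFrame(points,
                           columns=["p_random", "p_serial", "p_spatial"])
    surface["mse"] = mean_err
    best = MixtureParams(*best_triple, n_persist=n_persist)
    return MixtureFitResult(best, surface, grid.repetitions,
                            per_rep_best=per_rep)


def scan_n(target: SummarySet,
           schedule: pd.DataFrame,
           grid: GridFitConfig = GridFitConfig(),
           seed: int | np.random.SeedSequence = 0,
           config: MazeConfig = DEFAULT_MAZE,
           strategy_params: StrategyParams = StrategyParams(),
           ) -> MixtureFitResult:
    """Repeat the grid search for every N in ``grid.n_range``; pick the N
    (and its best triple) with the lowest averaged minimal error.
    Ties resolve toward the smaller N."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(grid.n_range))
    fits = [
        fit_mixture_grid(target, schedule, grid, n, child,
                         config, strategy_params)
        for n, child in zip(grid.n_range, children)
    ]
    err_by_n = pd.Series([f.min_mse for f in fits], index=list(grid.n_range),
                         name="mse")
    best_i = int(np.argmin(err_by_n.to_numpy()))
    best_fit = fits[best_i]
    return MixtureFitResult(best_fit.best, best_fit.error_surface,
                            grid.repetitions,
                            per_rep_best=best_fit.per_rep_best,
                            error_by_n=err_by_n)


class MixtureModel:
    """Mixture-of-strategies model bound to an observed trial set.

    Parameters
    ----------
    data : Dataset
        Complete trials whose summary distributions are the fitting target.
    schedule : DataFrame, optional
        Start schedule used for the fitting simulations (columns mouse_id,
        day, trial, start).  Defaults to the schedule of ``data`` itself,
        matching the estimator's use of the experimental start positions.
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
        self.target = summarize(data, config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MixtureModel":
        return cls(Dataset.from_dataframe(df), **kwargs)

    def fit(self, n_persist: int = 6,
            grid: GridFitConfig = GridFitConfig(),
            seed: int | np.random.SeedSequence = 0) -> "MixtureResults":
        res = fit_mixture_grid(self.target, self.schedule, grid, n_persist,
                               seed, self.config, self.strategy_params)
        return MixtureResults(self, res, grid, seed)

    def fit_scan_n(self, grid: GridFitConfig = GridFitConfig(),
                   seed: int | np.random.SeedSequence = 0) -> "MixtureResults":
        res = scan_n(self.target, self.schedule, grid, seed,
                     self.config, self.strategy_params)
        return MixtureResults(self, res, grid, seed)


class MixtureResults:
    """Fitted mixture model: estimates, repetition spread and diagnostics."""

    def __init__(self, model: MixtureModel, fit: MixtureFitResult,
                 grid: GridFitConfig, seed):
        self.model = model
        self._fit = fit
        self.grid = grid
        self.seed = seed

    @property
    def params(self) -> MixtureParams:
        return self._fit.best

    @property
    def error_surface(self) -> pd.DataFrame:
        return self._fit.error_surface

    @property
    def error_by_n(self) -> pd.Series | None:
        return self._fit.error_by_n

    @property
    def min_mse(self) -> float:
        return self._fit.min_mse

    def params_spread(self) -> pd.Series:
        """SD of the per-repetition argmin triples (dispersion diagnostic)."""
        if self._fit.per_rep_best is None:
            return pd.Series(dtype=float)
        return self._fit.per_rep_best.std(ddof=1)

    def simulate(self, rng: np.random.Generator,
                 schedule: pd.DataFrame | None = None) -> Dataset:
        """Simulate a dataset from the fitted parameters."""
        return simulate_mixture_dataset(
            self.params, schedule if schedule is not None else
            self.model.schedule, rng, self.model.config,
            self.model.strategy_params)

    def summary(self) -> str:
        p = self.params
        spread = self.params_spread()
        lines = [
            "Mixture-of-strategies fit (exhaustive grid search)",
            "=" * 54,
            f"trials in target:        {len(self.model.schedule):>8d}",
            f"grid increment:          {self.grid.increment:>8d} %",
            f"repetitions averaged:    {self._fit.repetitions_used:>8d}",
            "-" * 54,
            f"{'strategy':<12}{'estimate (%)':>14}{'rep. SD':>12}",
        ]
        for name, val in zip(("random", "serial", "spatial"), p.probs):
            sd = spread.get(f"p_{name}", float("nan"))
            lines.append(f"{name:<12}{val:>14.1f}{sd:>12.2f}")
        lines.append("-" * 54)
        lines.append(f"persistence N:           {p.n_persist:>8d}")
        lines.append(f"minimal averaged MSE:    {self.min_mse:>12.3e}")
        if self.error_by_n is not None:
            trail = ", ".join(f"{n}:{v:.2e}"
                              for n, v in self.error_by_n.items())
            lines.append(f"MSE by N: {trail}")
        return "\n".join(lines)

    def plot_error_surface(self, ax=None):
        """Ternary-style scatter of the averaged MSE over the simplex grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        surf = self.error_surface
        sc = ax.scatter(surf["p_random"], surf["p_serial"],
                        c=surf["mse"], cmap="viridis", s=18)
        ax.plot(self.params.p_random, self.params.p_serial, "r*",
                markersize=12)
        ax.set_xlabel("P_random (%)")
        ax.set_ylabel("P_serial (%)")
        ax.figure.colorbar(sc, ax=ax, label="mean squared error")
        return ax

    def plot_error_by_n(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.error_by_n is None:
            raise ValueError("no N-scan was run for this fit")
        self.error_by_n.plot(ax=ax, marker="o")
        ax.set_xlabel("persistence N (segments)")
        ax.set_ylabel("minimal averaged MSE")
        return ax
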