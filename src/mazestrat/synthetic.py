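"""Ground-truth-labelled synthetic data emulating the study's structure.

The generator reproduces the experimental design — 19 mice (10 male, 9
female), 10 trials per day over 19 days, a per-day random start sequence
shared by all mice with every start at least 2 door-intervals from the goal
— and drives the mixture or Markov simulators with known parameters, so the
whole pipeline (segmentation, summaries, both fits, the classifier) can be
exercised and its parameter recovery measured without the original animal
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import DEFAULT_MAZE, Dataset, MazeConfig, Trial, circular_distance
from .mixture import MixtureParams, simulate_mixture_dataset
from .markov import MarkovParams, simulate_markov_dataset
from .strategies import StrategyParams

__all__ = [
    "ExperimentPlan",
    "make_start_schedule",
    "generate_dataset",
    "synthesize_xy_trajectory",
]


@dataclass(frozen=True)
class ExperimentPlan:
    """Study-structure parameters of the synthetic experiment.

    ``params`` holds the generating model: a single :class:`MixtureParams`
    or :class:`MarkovParams` applied to all days, or a mapping day ->
    params.  ``n_male`` of the mice are labelled male, the rest female.
    """

    n_mice: int = 19
    trials_per_day: int = 10
    days: int = 19
    min_start_distance: int = 2
    n_male: int | None = None   # defaults to 10, capped at n_mice
    params: object = field(
        default_factory=lambda: MixtureParams(58.2, 28.4, 13.4, n_persist=6))

    def __post_init__(self) -> None:
        if min(self.n_mice, self.trials_per_day, self.days) < 1:
            raise ValueError("counts must be >= 1")
        if self.min_start_distance < 1:
            raise ValueError("min_start_distance must be >= 1")
        if self.n_male is None:
            object.__setattr__(self, "n_male", min(10, self.n_mice))
        if not 0 <= self.n_male <= self.n_mice:
            raise ValueError("n_male must be in 0..n_mice")

    def mouse_ids(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_male)] + \
               [f"F{i + 1:02d}" for i in range(self.n_mice - self.n_male)]

    def sex_labels(self) -> dict[str, str]:
        return {m: ("M" if m.startswith("M") else "F")
                for m in self.mouse_ids()}

    def params_for_day(self, day: int):
        if isinstance(self.params, dict):
            return self.params[day]
        return self.params


def make_start_schedule(plan: ExperimentPlan,
                        rng: np.random.Generator,
                        config: MazeConfig = DEFAULT_MAZE) -> pd.DataFrame:
    """Start vestibule per (mouse, day, trial).

    Starts are drawn uniformly among vestibules at least
    ``min_start_distance`` door-intervals from the goal; each day has one
    random trial-ordered start sequence shared by all mice.
    """
    if plan.min_start_distance > config.max_span:
        raise ValueError("min_start_distance exceeds the maximal door "
                         "distance on the cycle")
    v = np.arange(config.n_vestibules)
    allowed = v[np.asarray(circular_distance(v, config.goal_index, config))
                >= plan.min_start_distance]
    rows = []
    for day in range(1, plan.days + 1):
        day_starts = rng.choice(allowed, size=plan.trials_per_day,
                                replace=True)
        for mouse in plan.mouse_ids():
            for trial, start in enumerate(day_starts, start=1):
                rows.append((mouse, day, trial, int(start)))
    return pd.DataFrame(rows, columns=["mouse_id", "day", "trial", "start"])


def generate_dataset(plan: ExperimentPlan, rng: np.random.Generator,
                     config: MazeConfig = DEFAULT_MAZE,
                     strategy_params: StrategyParams = StrategyParams(),
                     schedule: pd.DataFrame | None = None) -> Dataset:
    """Simulate the full planned experiment with ground-truth labels.

    Raises if more than 1 % of trials hit the step guard (a truncation rate
    that high indicates a misconfigured guard, not sampling noise).
    """
    if schedule is None:
        schedule = make_start_schedule(plan, rng, config)
    trials: list[Trial] = []
    for day, day_sched in schedule.groupby("day", sort=True):
        params = plan.params_for_day(int(day))
        if isinstance(params, MixtureParams):
            ds = simulate_mixture_dataset(params, day_sched, rng, config,
                                          strategy_params)
        elif isinstance(params, MarkovParams):
            ds = simulate_markov_dataset(params, day_sched, rng, config,
                                         strategy_params)
        else:
            raise TypeError("plan.params must be MixtureParams or "
                            "MarkovParams")
        trials.extend(ds.trials)
    n_trunc = sum(t.truncated for t in trials)
    if n_trunc > 0.01 * len(trials):
        raise RuntimeError(
            f"{n_trunc}/{len(trials)} trials truncated by the step guard; "
            "check max_steps_per_trial")
    return Dataset(trials, {"plan": "synthetic", "sex": plan.sex_labels()})


def synthesize_xy_trajectory(trial: Trial,
                             config: MazeConfig = DEFAULT_MAZE,
                             rng: np.random.Generator | None = None,
                             jitter_sd_cm: float = 0.5,
                             arc_radius_frac: float = 0.9,
                             excursion_cm: float = 3.0,
                             speed_cm_s: float = 25.0) -> "XYTrajectory":
    """Piecewise xy fixture realising a trial's vestibule sequence.

    The path pokes radially beyond the visit threshold at each visited
    vestibule's sector centre and travels between vestibules on an inner
    arc (``arc_radius_frac`` x threshold) in the direction given by the
    segment's sign, sampled at the maze frame rate with optional Gaussian
    positional jitter.  Defaults keep every threshold crossing unambiguous,
    so segmentation must recover the generating sequence exactly.
    """
    from .segmentation import XYTrajectory, segments_from_visits

    r_in = arc_radius_frac * config.visit_radius_cm
    r_out = config.visit_radius_cm + excursion_cm
    seq = [trial.start] + list(trial.visits)
    segs = segments_from_visits(trial.start, trial.visits, config)
    pts: list[tuple[float, float]] = []

    def polar(radius: float, angle_deg: float) -> tuple[float, float]:
        a = np.radians(angle_deg)
        return (radius * np.cos(a), radius * np.sin(a))

    ang = float(config.vestibule_angle_deg(seq[0]))
    pts.append(polar(r_out, ang))
    step_deg = 360.0 / config.n_vestibules
    for size in segs:
        pts.append(polar(r_in, ang))
        # positive (clockwise) segments sweep toward smaller math angles
        sweep = -step_deg * size
        n_arc = max(2, int(abs(sweep) / 2.0))
        for a in np.linspace(ang, ang + sweep, n_arc + 1)[1:]:
            pts.append(polar(r_in, float(a)))
        ang += sweep
        pts.append(polar(r_out, ang))

    pts_arr = np.asarray(pts, dtype=float)
    d = np.hypot(*np.diff(pts_arr, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    ds = speed_cm_s / config.sample_rate_hz
    grid = np.arange(0.0, s[-1] + ds, ds)
    x = np.interp(grid, s, pts_arr[:, 0])
    y = np.interp(grid, s, pts_arr[:, 1])
    if jitter_sd_cm > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + rng.normal(0.0, jitter_sd_cm, x.size)
        y = y + rng.normal(0.0, jitter_sd_cm, y.size)
    t = np.arange(x.size) / config.sample_rate_hz
    return XYTrajectory(trial.mouse_id, trial.day, trial.trial, t, x, y)
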