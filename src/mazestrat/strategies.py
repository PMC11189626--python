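"""The three stochastic processes that draw the next vestibule.

Each process maps the current vestibule to the next one:

* **random** — uniform over the other 23 vestibules (unstructured search),
* **spatial** — goal-biased: the probability of a vestibule decays as
  ``exp(-d/tau)`` with its door-distance ``d`` to the goal (allocentric
  search), redrawn when the current vestibule comes up,
* **serial** — the current index is incremented by a small noisy step ``S``
  drawn from a direction-specific rounded normal (consecutive-door search);
  in unified mode the step sign is drawn first with probability ``p_cw`` of
  being positive (clockwise).

No process ever re-selects the current vestibule, so every realised segment
has a signed size in ±1..±12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maze import DEFAULT_MAZE, MazeConfig, Trial, circular_distance

__all__ = [
    "SpatialParams",
    "SerialParams",
    "StrategyParams",
    "spatial_weights",
    "draw_random_step",
    "draw_spatial_step",
    "draw_serial_step",
    "run_process_until_goal",
    "MIXTURE_STRATEGIES",
    "MARKOV_STRATEGIES",
]

#: strategy label order used by the mixture model (3 processes)
MIXTURE_STRATEGIES = ("random", "serial", "spatial")
#: strategy label order used by the Markov-chain model (4 processes)
MARKOV_STRATEGIES = ("random", "serial_cw", "serial_ccw", "spatial")


@dataclass(frozen=True)
class SpatialParams:
    """Goal-distance decay of the spatial process (tau in door-intervals)."""

    tau: float = 2.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class SerialParams:
    """Step statistics of the serial process.

    The clockwise step is centred at +1.2 door-intervals (SD 1.2), the
    counterclockwise step at -2 (SD 1.5), and in unified mode the sign is
    positive with probability 0.8 — values chosen to reproduce the twin
    peaks of the observed segment-size distribution.
    """

    center_cw: float = 1.2
    center_ccw: float = -2.0
    sd_cw: float = 1.2
    sd_ccw: float = 1.5
    p_cw: float = 0.8

    def __post_init__(self) -> None:
        if self.sd_cw <= 0 or self.sd_ccw <= 0:
            raise ValueError("step SDs must be positive")
        if not 0 <= self.p_cw <= 1:
            raise ValueError("p_cw must be a probability")


@dataclass(frozen=True)
class StrategyParams:
    """All stochastic-process parameters plus the per-trial step guard."""

    spatial: SpatialParams = field(default_factory=SpatialParams)
    serial: SerialParams = field(default_factory=SerialParams)
    max_steps_per_trial: int = 1000

    def __post_init__(self) -> None:
        if self.max_steps_per_trial < 1:
            raise ValueError("max_steps_per_trial must be >= 1")


def spatial_weights(config: MazeConfig = DEFAULT_MAZE,
                    params: SpatialParams = SpatialParams()) -> np.ndarray:
    """Unnormalised spatial-process weight of every vestibule.

    ``w(v) = exp(-circular_distance(v, goal) / tau)`` — two symmetric
    exponential flanks peaking at the goal.
    """
    v = np.arange(config.n_vestibules)
    d = circular_distance(v, config.goal_index, config)
    return np.exp(-np.asarray(d, dtype=float) / params.tau)


def draw_random_step(current: int, rng: np.random.Generator,
                     config: MazeConfig = DEFAULT_MAZE) -> int:
    """Uniform draw over the ``n - 1`` vestibules other than ``current``."""
    _check(current, config)
    r = int(rng.integers(0, config.n_vestibules - 1))
    return r + 1 if r >= current else r


def draw_spatial_step(current: int, rng: np.random.Generator,
                      config: MazeConfig = DEFAULT_MAZE,
                      params: SpatialParams = SpatialParams()) -> int:
    """Goal-biased categorical draw, excluding the current vestibule.

    Implemented as an exact categorical draw over the 23 allowed vestibules
    with the exponential weights renormalised — the distribution induced by
    drawing from all 24 and redrawing while the current vestibule comes up.
    """
    _check(current, config)
    w = spatial_weights(config, params).copy()
    w[current] = 0.0
    return int(rng.choice(config.n_vestibules, p=w / w.sum()))


def draw_serial_step(current: int, rng: np.random.Generator,
                     config: MazeConfig = DEFAULT_MAZE,
                     params: SerialParams = SerialParams(),
                     direction: str = "unified") -> tuple[int, int]:
    """Serial step: increment ``current`` by a noisy direction-biased step.

    Parameters
    ----------
    direction : {"unified", "cw", "ccw"}
        ``unified`` draws the sign first (P(+) = ``p_cw``) then the step
        magnitude from that direction's rounded normal; ``cw``/``ccw`` fix
        the direction (used by the Markov model's split serial strategies).

    Returns
    -------
    (next_vestibule, step) where ``step`` is the realised signed step S.
    The step is redrawn until it is nonzero, its sign matches the drawn (or
    fixed) direction, and it moves to a different vestibule.
    """
    _check(current, config)
    if direction not in ("unified", "cw", "ccw"):
        raise ValueError("direction must be 'unified', 'cw' or 'ccw'")
    if direction == "unified":
        sign = 1 if rng.uniform(0.0, 1.0) < params.p_cw else -1
    else:
        sign = 1 if direction == "cw" else -1
    center = params.center_cw if sign > 0 else params.center_ccw
    sd = params.sd_cw if sign > 0 else params.sd_ccw
    n = config.n_vestibules
    while True:
        s = int(np.rint(center + sd * rng.standard_normal()))
        if s == 0 or (s > 0) != (sign > 0):
            continue
        if s % n == 0:  # full lap would land back on current
            continue
        return (current + s) % n, s


_DRAWERS = {
    "random": lambda cur, rng, cfg, par: draw_random_step(cur, rng, cfg),
    "spatial": lambda cur, rng, cfg, par: draw_spatial_step(
        cur, rng, cfg, par.spatial),
    "serial": lambda cur, rng, cfg, par: draw_serial_step(
        cur, rng, cfg, par.serial, "unified")[0],
    "serial_cw": lambda cur, rng, cfg, par: draw_serial_step(
        cur, rng, cfg, par.serial, "cw")[0],
    "serial_ccw": lambda cur, rng, cfg, par: draw_serial_step(
        cur, rng, cfg, par.serial, "ccw")[0],
}


def run_process_until_goal(process: str, start: int,
                           rng: np.random.Generator,
                           config: MazeConfig = DEFAULT_MAZE,
                           params: StrategyParams = StrategyParams(),
                           *, mouse_id: str = "sim", day: int = 1,
                           trial: int = 1, strict: bool = False) -> Trial:
    """Run one stochastic process recursively until the goal is reached.

    The process draws the next vestibule from the current one until the goal
    comes up or ``params.max_steps_per_trial`` is exceeded (then the trial is
    returned with ``truncated=True``, or an error is raised in strict mode).
    ``start == goal`` yields a degenerate zero-segment trial.
    """
    if process not in _DRAWERS:
        raise ValueError(f"unknown process {process!r}")
    _check(start, config)
    visits: list[int] = []
    current = start
    truncated = False
    if start != config.goal_index:
        for _ in range(params.max_steps_per_trial):
            current = _DRAWERS[process](current, rng, config, params)
            visits.append(current)
            if current == config.goal_index:
                break
        else:
            truncated = True
            if strict:
                raise RuntimeError(
                    f"{process} process exceeded "
                    f"{params.max_steps_per_trial} steps"
                )
    return Trial(mouse_id, day, trial, start, tuple(visits),
                 strategy_labels=(process,) * len(visits),
                 truncated=truncated)


def _check(current: int, config: MazeConfig) -> None:
    if not 0 <= current < config.n_vestibules:
        raise ValueError("vestibule index out of range")
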