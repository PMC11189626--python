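"""Vectorised batch simulation of vestibule sequences.

The per-step draws in :mod:`mazestrat.strategies` define the processes; this
module advances *all trials of a dataset in lock-step* with array operations,
which is what makes exhaustive grid search and the genetic algorithm cheap.
The batch drawers sample from exactly the same per-step distributions as the
scalar ones (tested against them); only the order in which the underlying
random stream is consumed differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maze import DEFAULT_MAZE, Dataset, MazeConfig, Trial
from .strategies import (
    MARKOV_STRATEGIES,
    MIXTURE_STRATEGIES,
    SerialParams,
    SpatialParams,
    StrategyParams,
    spatial_weights,
)

__all__ = [
    "SequenceBatch",
    "simulate_mixture_batch",
    "simulate_markov_batch",
    "simulate_process_batch",
]

_PAD = -1


@dataclass
class SequenceBatch:
    """Padded array view of a set of trials.

    ``visits[i, :lengths[i]]`` is trial *i*'s visit sequence (start excluded);
    entries beyond the length are padding.  ``labels`` holds integer strategy
    codes per segment (index into ``label_names``) when available.
    """

    starts: np.ndarray            # (n,) int
    visits: np.ndarray            # (n, L) int, padded with -1
    lengths: np.ndarray           # (n,) int
    truncated: np.ndarray         # (n,) bool
    labels: np.ndarray | None = None   # (n, L) int, padded with -1
    label_names: tuple[str, ...] | None = None

    @property
    def n_trials(self) -> int:
        return int(self.starts.size)

    def segment_sizes(self, config: MazeConfig = DEFAULT_MAZE) -> np.ndarray:
        """Signed segment sizes, padded with 0 beyond each trial's length."""
        n_v = config.n_vestibules
        prev = np.concatenate([self.starts[:, None], self.visits[:, :-1]],
                              axis=1)
        cw = (self.visits - prev) % n_v
        seg = np.where(cw <= n_v // 2, cw, cw - n_v)
        mask = np.arange(self.visits.shape[1])[None, :] < self.lengths[:, None]
        return np.where(mask, seg, 0)

    def mask(self) -> np.ndarray:
        return np.arange(self.visits.shape[1])[None, :] < self.lengths[:, None]

    @classmethod
    def from_dataset(cls, dataset: Dataset | list[Trial]) -> "SequenceBatch":
        trials = list(dataset)
        if not trials:
            raise ValueError("empty dataset")
        n = len(trials)
        L = max((t.n_segments for t in trials), default=0) or 1
        starts = np.array([t.start for t in trials], dtype=np.int64)
        visits = np.full((n, L), _PAD, dtype=np.int64)
        lengths = np.array([t.n_segments for t in trials], dtype=np.int64)
        trunc = np.array([t.truncated for t in trials], dtype=bool)
        for i, t in enumerate(trials):
            visits[i, : t.n_segments] = t.visits
        return cls(starts, visits, lengths, trunc)

    def to_trials(self, *, mouse_ids=None, days=None, trial_nums=None
                  ) -> list[Trial]:
        out = []
        for i in range(self.n_trials):
            k = int(self.lengths[i])
            labels = None
            if self.labels is not None and self.label_names is not None:
                labels = tuple(self.label_names[c]
                               for c in self.labels[i, :k])
            out.append(Trial(
                mouse_id=str(mouse_ids[i]) if mouse_ids is not None else "sim",
                day=int(days[i]) if days is not None else 1,
                trial=int(trial_nums[i]) if trial_nums is not None else i + 1,
                start=int(self.starts[i]),
                visits=tuple(int(v) for v in self.visits[i, :k]),
                strategy_labels=labels,
                truncated=bool(self.truncated[i]),
            ))
        return out


# ---------------------------------------------------------------------------
# vectorised per-step drawers


def _batch_random(rng: np.random.Generator, current: np.ndarray,
                  n_vest: int) -> np.ndarray:
    r = rng.integers(0, n_vest - 1, size=current.size)
    return r + (r >= current)


def _spatial_cum(config: MazeConfig, tau: float) -> np.ndarray:
    """Per-current-vestibule cumulative probabilities (n x n), current excluded."""
    base = spatial_weights(config, SpatialParams(tau=tau))
    n = config.n_vestibules
    W = np.tile(base, (n, 1))
    W[np.arange(n), np.arange(n)] = 0.0
    cum = np.cumsum(W / W.sum(axis=1, keepdims=True), axis=1)
    cum[:, -1] = 1.0
    return cum


def _batch_categorical(rng: np.random.Generator, cum_rows: np.ndarray
                       ) -> np.ndarray:
    u = rng.random(cum_rows.shape[0])
    return (u[:, None] > cum_rows).sum(axis=1)


def _batch_serial(rng: np.random.Generator, current: np.ndarray,
                  signs: np.ndarray, params: SerialParams,
                  n_vest: int) -> np.ndarray:
    """Vectorised serial step with rejection until valid (nonzero, sign-matching)."""
    S = np.zeros(current.size, dtype=np.int64)
    todo = np.ones(current.size, dtype=bool)
    while todo.any():
        idx = np.flatnonzero(todo)
        pos = signs[idx] > 0
        center = np.where(pos, params.center_cw, params.center_ccw)
        sd = np.where(pos, params.sd_cw, params.sd_ccw)
        s = np.rint(center + sd * rng.standard_normal(idx.size)).astype(np.int64)
        ok = (s != 0) & ((s > 0) == pos) & (s % n_vest != 0)
        S[idx[ok]] = s[ok]
        todo[idx[ok]] = False
    return (current + S) % n_vest


# ---------------------------------------------------------------------------
# simulators


def _assemble(n: int, starts: np.ndarray, steps: list, active_left: np.ndarray,
              label_names: tuple[str, ...]) -> SequenceBatch:
    lengths = np.zeros(n, dtype=np.int64)
    L = max(len(steps), 1)
    visits = np.full((n, L), _PAD, dtype=np.int64)
    labels = np.full((n, L), _PAD, dtype=np.int64)
    for t, (idx, nxt, lab) in enumerate(steps):
        visits[idx, t] = nxt
        labels[idx, t] = lab
        lengths[idx] = t + 1
    truncated = np.zeros(n, dtype=bool)
    truncated[active_left] = True
    return SequenceBatch(starts.astype(np.int64), visits, lengths, truncated,
                         labels=labels, label_names=label_names)


def simulate_mixture_batch(probs: tuple[float, float, float],
                           n_persist: int,
                           starts: np.ndarray,
                           rng: np.random.Generator,
                           config: MazeConfig = DEFAULT_MAZE,
                           params: StrategyParams = StrategyParams(),
                           ) -> SequenceBatch:
    """Simulate one mixture-model trial per entry of ``starts``.

    ``probs`` are (P_random, P_serial, P_spatial) in percent.  At the start
    of every block a strategy is drawn (random if x < P_random, serial if
    x > P_random + P_spatial, else spatial, with x uniform on [0, 100)), and
    its process generates the next ``n_persist`` segments; a trial terminates
    the moment the goal is visited.
    """
    p_random, p_serial, p_spatial = (float(p) for p in probs)
    if min(p_random, p_serial, p_spatial) < 0 or \
            abs(p_random + p_serial + p_spatial - 100.0) > 1e-6:
        raise ValueError("strategy probabilities must be >= 0 and sum to 100")
    if n_persist < 1:
        raise ValueError("n_persist must be >= 1")
    starts = np.asarray(starts, dtype=np.int64)
    n = starts.size
    n_vest = config.n_vestibules
    goal = config.goal_index
    cum = _spatial_cum(config, params.spatial.tau)

    current = starts.copy()
    rem = np.zeros(n, dtype=np.int64)
    strat = np.zeros(n, dtype=np.int64)
    active = np.flatnonzero(starts != goal)
    steps: list = []
    for _ in range(params.max_steps_per_trial):
        if active.size == 0:
            break
        need = rem[active] == 0
        if need.any():
            x = rng.uniform(0.0, 100.0, int(need.sum()))
            new = np.where(x < p_random, 0,
                           np.where(x > p_random + p_spatial, 1, 2))
            strat[active[need]] = new
            rem[active[need]] = n_persist
        sc = strat[active]
        nxt = np.empty(active.size, dtype=np.int64)
        m = sc == 0
        if m.any():
            nxt[m] = _batch_random(rng, current[active[m]], n_vest)
        m = sc == 1
        if m.any():
            signs = np.where(rng.random(int(m.sum())) < params.serial.p_cw,
                             1, -1)
            nxt[m] = _batch_serial(rng, current[active[m]], signs,
                                   params.serial, n_vest)
        m = sc == 2
        if m.any():
            nxt[m] = _batch_categorical(rng, cum[current[active[m]]])
        rem[active] -= 1
        current[active] = nxt
        steps.append((active, nxt, sc))
        active = active[nxt != goal]
    return _assemble(n, starts, steps, active, MIXTURE_STRATEGIES)


def simulate_markov_batch(initial: np.ndarray,
                          transitions: np.ndarray,
                          starts: np.ndarray,
                          rng: np.random.Generator,
                          config: MazeConfig = DEFAULT_MAZE,
                          params: StrategyParams = StrategyParams(),
                          ) -> SequenceBatch:
    """Simulate one Markov-chain trial per entry of ``starts``.

    Strategies are ordered (random, serial_cw, serial_ccw, spatial).  The
    first segment's strategy is drawn from ``initial`` (length 4); every
    subsequent segment's from ``transitions[previous]`` (4 x 4, row
    stochastic).  Serial strategies are direction-fixed.
    """
    initial = np.asarray(initial, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    if initial.shape != (4,) or transitions.shape != (4, 4):
        raise ValueError("expected initial (4,) and transitions (4, 4)")
    for row in [initial, *transitions]:
        if (row < -1e-9).any() or abs(row.sum() - 1.0) > 1e-6:
            raise ValueError("probability rows must be >= 0 and sum to 1")
    starts = np.asarray(starts, dtype=np.int64)
    n = starts.size
    n_vest = config.n_vestibules
    goal = config.goal_index
    cum_spatial = _spatial_cum(config, params.spatial.tau)
    cum_init = np.cumsum(initial)
    cum_init[-1] = 1.0
    cum_trans = np.cumsum(transitions, axis=1)
    cum_trans[:, -1] = 1.0

    current = starts.copy()
    strat = np.zeros(n, dtype=np.int64)
    active = np.flatnonzero(starts != goal)
    steps: list = []
    first = True
    for _ in range(params.max_steps_per_trial):
        if active.size == 0:
            break
        if first:
            strat[active] = _batch_categorical(
                rng, np.tile(cum_init, (active.size, 1)))
            first = False
        else:
            strat[active] = _batch_categorical(rng, cum_trans[strat[active]])
        sc = strat[active]
        nxt = np.empty(active.size, dtype=np.int64)
        m = sc == 0
        if m.any():
            nxt[m] = _batch_random(rng, current[active[m]], n_vest)
        for code, sign in ((1, 1), (2, -1)):
            m = sc == code
            if m.any():
                signs = np.full(int(m.sum()), sign, dtype=np.int64)
                nxt[m] = _batch_serial(rng, current[active[m]], signs,
                                       params.serial, n_vest)
        m = sc == 3
        if m.any():
            nxt[m] = _batch_categorical(rng, cum_spatial[current[active[m]]])
        current[active] = nxt
        steps.append((active, nxt, sc))
        active = active[nxt != goal]
    return _assemble(n, starts, steps, active, MARKOV_STRATEGIES)


def simulate_process_batch(process: str, starts: np.ndarray,
                           rng: np.random.Generator,
                           config: MazeConfig = DEFAULT_MAZE,
                           params: StrategyParams = StrategyParams(),
                           ) -> SequenceBatch:
    """Simulate a pure single-process dataset (one trial per start)."""
    pure = {
        "random": ((100.0, 0.0, 0.0), MIXTURE_STRATEGIES),
        "serial": ((0.0, 100.0, 0.0), MIXTURE_STRATEGIES),
        "spatial": ((0.0, 0.0, 100.0), MIXTURE_STRATEGIES),
    }
    if process in pure:
        probs, _ = pure[process]
        return simulate_mixture_batch(probs, params.max_steps_per_trial,
                                      starts, rng, config, params)
    if process in ("serial_cw", "serial_ccw"):
        code = MARKOV_STRATEGIES.index(process)
        initial = np.eye(4)[code]
        return simulate_markov_batch(initial, np.eye(4), starts, rng,
                                     config, params)
    raise ValueError(f"unknown process {process!r}")
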