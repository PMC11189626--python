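"""Arena geometry, vestibule indexing and the core sequence containers.

The maze is a circular arena whose periphery carries ``n_vestibules`` (24 by
default) evenly spaced entry chambers ("vestibules").  All analyses work in a
goal-centred frame: vestibules are labelled 0..23 with the goal at index 0,
and indices increase in the clockwise direction, so a positive step of ``k``
door-intervals means ``k`` doors clockwise.  A trial is the ordered list of
vestibules an animal (or a simulated process) visits on its way from a start
vestibule to the goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MazeConfig",
    "Trial",
    "Dataset",
    "circular_distance",
    "signed_displacement",
    "DEFAULT_MAZE",
]


@dataclass(frozen=True)
class MazeConfig:
    """Geometry and indexing conventions of the automated maze.

    Parameters
    ----------
    n_vestibules : int
        Number of peripheral entry chambers (doors).
    goal_index : int
        Label of the goal vestibule in the goal-centred frame.
    visit_radius_cm : float
        Radial distance from the arena centre beyond which the animal is
        considered inside a vestibule (entry/exit threshold).
    arena_radius_cm : float
        Radius of the arena floor (95 cm wide disc).
    sample_rate_hz : float
        Nominal sampling rate of xy tracking.
    """

    n_vestibules: int = 24
    goal_index: int = 0
    visit_radius_cm: float = 47.5
    arena_radius_cm: float = 47.5
    sample_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        if self.n_vestibules < 3:
            raise ValueError("n_vestibules must be >= 3")
        if not 0 <= self.goal_index < self.n_vestibules:
            raise ValueError("goal_index out of range")
        if self.visit_radius_cm <= 0:
            raise ValueError("visit_radius_cm must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def max_span(self) -> int:
        """Largest door-distance on the cycle (12 for 24 vestibules)."""
        return self.n_vestibules // 2

    def vestibule_angle_deg(self, v: int | np.ndarray) -> np.ndarray:
        """Mathematical angle (degrees, CCW-positive) of a vestibule centre.

        The goal sits at 90 deg (top of the arena); indices increase
        clockwise, i.e. toward smaller mathematical angles.
        """
        step = 360.0 / self.n_vestibules
        return np.asarray(90.0 - step * np.asarray(v), dtype=float)


DEFAULT_MAZE = MazeConfig()


def _check_indices(config: MazeConfig, *indices: int | np.ndarray) -> None:
    for idx in indices:
        a = np.asarray(idx)
        if a.size and ((a < 0).any() or (a >= config.n_vestibules).any()):
            raise ValueError(
                f"vestibule index out of range 0..{config.n_vestibules - 1}"
            )


def circular_distance(a, b, config: MazeConfig = DEFAULT_MAZE):
    """Door-distance between two vestibules on the cycle (0..n/2).

    Accepts scalars or arrays; the distance is the smaller of the clockwise
    and counterclockwise door counts.
    """
    _check_indices(config, a, b)
    n = config.n_vestibules
    d = np.abs(np.asarray(a) - np.asarray(b)) % n
    out = np.minimum(d, n - d)
    return out.item() if np.isscalar(a) and np.isscalar(b) else out


def signed_displacement(a, b, config: MazeConfig = DEFAULT_MAZE):
    """Signed door-step from vestibule ``a`` to ``b`` along the shorter route.

    Positive values are clockwise (index-increasing) steps, negative values
    counterclockwise; the magnitude equals :func:`circular_distance`.  The
    antipodal tie (distance n/2) resolves to the positive (clockwise) sign,
    which keeps sequence-only segmentation deterministic.
    """
    _check_indices(config, a, b)
    n = config.n_vestibules
    cw = (np.asarray(b) - np.asarray(a)) % n
    out = np.where(cw <= n // 2, cw, cw - n).astype(np.int64)
    return int(out) if np.isscalar(a) and np.isscalar(b) else out


@dataclass
class Trial:
    """One navigation trial: a start vestibule and the ordered visits.

    ``visits`` excludes the start and, for a complete trial, ends at the goal.
    ``strategy_labels`` optionally carries one label per segment (ground truth
    from a generator or a model assignment).  ``truncated`` flags simulated
    trials cut off by the step guard before reaching the goal.
    """

    mouse_id: str
    day: int
    trial: int
    start: int
    visits: tuple[int, ...]
    strategy_labels: tuple[str, ...] | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.visits = tuple(int(v) for v in self.visits)
        if self.strategy_labels is not None:
            self.strategy_labels = tuple(self.strategy_labels)
            if len(self.strategy_labels) != len(self.visits):
                raise ValueError("one strategy label per segment required")
        seq = (self.start,) + self.visits
        for prev, cur in zip(seq, seq[1:]):
            if prev == cur:
                raise ValueError("consecutive repeated vestibule in trial")

    @property
    def n_segments(self) -> int:
        return len(self.visits)

    def is_complete(self, config: MazeConfig = DEFAULT_MAZE) -> bool:
        return (
            not self.truncated
            and len(self.visits) > 0
            and self.visits[-1] == config.goal_index
        ) or (len(self.visits) == 0 and self.start == config.goal_index)

    def key(self) -> tuple[str, int, int]:
        return (self.mouse_id, self.day, self.trial)


@dataclass
class Dataset:
    """A collection of trials with provenance metadata.

    Trials are keyed by (mouse_id, day, trial); keys must be unique.
    """

    trials: list[Trial] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [t.key() for t in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("(mouse_id, day, trial) keys must be unique")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def days(self) -> list[int]:
        return sorted({t.day for t in self.trials})

    def filter(self, *, days: Iterable[int] | None = None,
               mice: Iterable[str] | None = None) -> "Dataset":
        days = set(days) if days is not None else None
        mice = set(mice) if mice is not None else None
        kept = [
            t for t in self.trials
            if (days is None or t.day in days)
            and (mice is None or t.mouse_id in mice)
        ]
        return Dataset(kept, dict(self.metadata))

    def complete_trials(self, config: MazeConfig = DEFAULT_MAZE) -> list[Trial]:
        return [t for t in self.trials if t.is_complete(config)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format sequence table: one row per step, step_index 0 = start."""
        rows = []
        for t in self.trials:
            for i, v in enumerate((t.start,) + t.visits):
                rows.append((t.mouse_id, t.day, t.trial, i, v))
        return pd.DataFrame(
            rows, columns=["mouse_id", "day", "trial", "step_index", "vestibule"]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       metadata: Mapping | None = None) -> "Dataset":
        required = {"mouse_id", "day", "trial", "step_index", "vestibule"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        trials: list[Trial] = []
        for (mouse, day, trial), grp in df.groupby(
            ["mouse_id", "day", "trial"], sort=True
        ):
            grp = grp.sort_values("step_index")
            steps = grp["step_index"].to_numpy()
            if not np.array_equal(steps, np.arange(len(steps))):
                raise ValueError(
                    f"non-contiguous step_index for trial {(mouse, day, trial)}"
                )
            seq = grp["vestibule"].to_numpy(dtype=int)
            trials.append(
                Trial(str(mouse), int(day), int(trial),
                      int(seq[0]), tuple(seq[1:]))
            )
        return cls(trials, dict(metadata or {}))
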