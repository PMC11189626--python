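"""Trajectory segmentation: from timestamped xy paths to vestibule sequences.

A vestibule visit opens when the animal crosses the radial threshold
(``visit_radius_cm``, 47.5 cm) outward and closes at the next inward
crossing; the vestibule identity is the nearest of the 24 sector centres
(15 degrees apart) by angle at the crossing.  Segments between successive
visits are expressed as signed door-steps, and serial bouts are extracted
from the segment sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import DEFAULT_MAZE, MazeConfig, signed_displacement
from .summaries import serial_bouts  # re-exported for convenience

__all__ = [
    "XYTrajectory",
    "VisitEvent",
    "detect_vestibule_visits",
    "visit_sequence",
    "compute_path_length",
    "segments_from_visits",
    "serial_bouts",
]


@dataclass
class XYTrajectory:
    """Timestamped xy path (cm) in the arena-centred, goal-aligned frame."""

    mouse_id: str
    day: int
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size and (np.diff(self.t) <= 0).any():
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class VisitEvent:
    """One stay inside a vestibule: identity plus entry/exit times."""

    vestibule: int
    t_enter: float
    t_exit: float

    def __post_init__(self) -> None:
        if self.t_enter >= self.t_exit:
            raise ValueError("t_enter must precede t_exit")


def _vestibule_at(x: float, y: float, config: MazeConfig) -> int:
    step = 360.0 / config.n_vestibules
    theta = np.degrees(np.arctan2(y, x))
    return int(np.rint((90.0 - theta) / step)) % config.n_vestibules


def detect_vestibule_visits(traj: XYTrajectory,
                            config: MazeConfig = DEFAULT_MAZE
                            ) -> list[VisitEvent]:
    """Ordered vestibule visits of a trajectory.

    A visit spans a maximal run of samples at or beyond the radial
    threshold; identity is assigned from the angle at the first sample of
    the run.  A trajectory that starts outside the threshold opens a visit
    at its first sample; one that ends outside closes at its last sample.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    r = np.hypot(traj.x, traj.y)
    outside = r >= config.visit_radius_cm
    events: list[VisitEvent] = []
    i = 0
    n = len(traj)
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        # exit time: first sample back inside (or last sample of the path)
        t_exit = traj.t[j] if j < n else traj.t[n - 1]
        if t_exit <= traj.t[i]:
            t_exit = traj.t[i] + 0.5 / config.sample_rate_hz
        events.append(VisitEvent(_vestibule_at(traj.x[i], traj.y[i], config),
                                 traj.t[i], t_exit))
        i = j
    return events


def visit_sequence(events: list[VisitEvent],
                   collapse_repeats: bool = True) -> list[int]:
    """Vestibule sequence of a list of visit events.

    Immediate re-entries into the same vestibule are collapsed by default
    (they carry no segment of nonzero size).
    """
    seq: list[int] = []
    for e in events:
        if collapse_repeats and seq and seq[-1] == e.vestibule:
            continue
        seq.append(e.vestibule)
    return seq


def compute_path_length(x, y) -> float:
    """Integrated per-step Euclidean displacement of an xy path (cm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def segments_from_visits(start: int, visits,
                         config: MazeConfig = DEFAULT_MAZE) -> list[int]:
    """Signed segment sizes of a visit sequence.

    Element ``i`` is the signed door-step from the previous vestibule to
    visit ``i``; the trial length is the number of elements.  Consecutive
    equal vestibules are a domain error (segment size 0 is undefined).
    """
    seq = [start] + [int(v) for v in visits]
    out: list[int] = []
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError("consecutive equal vestibules give segment "
                             "size 0, which is undefined")
        out.append(signed_displacement(a, b, config))
    return out


def path_length_by_segment_size(traj: XYTrajectory,
                                config: MazeConfig = DEFAULT_MAZE
                                ) -> pd.DataFrame:
    """Per-segment path length paired with signed segment size.

    A descriptive statistic (not a fitting objective): each row is one
    running segment between consecutive vestibule visits, with the signed
    door-step it spans and the integrated path length of the xy slice
    between the exit of one vestibule and the entry of the next.
    """
    events = detect_vestibule_visits(traj, config)
    rows = []
    for a, b in zip(events, events[1:]):
        if a.vestibule == b.vestibule:
            continue
        m = (traj.t >= a.t_exit) & (traj.t <= b.t_enter)
        rows.append((signed_displacement(a.vestibule, b.vestibule, config),
                     compute_path_length(traj.x[m], traj.y[m])))
    return pd.DataFrame(rows, columns=["segment_size", "path_length_cm"])


def trajectory_from_frame(df: pd.DataFrame) -> list[XYTrajectory]:
    """Split a trajectory table (mouse_id, day, trial, t, x, y) into paths."""
    required = {"mouse_id", "day", "trial", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for (mouse, day, trial), grp in df.groupby(["mouse_id", "day", "trial"],
                                               sort=True):
        grp = grp.sort_values("t")
        out.append(XYTrajectory(str(mouse), int(day), int(trial),
                                grp["t"].to_numpy(), grp["x"].to_numpy(),
                                grp["y"].to_numpy()))
    return out
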