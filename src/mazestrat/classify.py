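"""Trial-wise baseline strategy classifier.

The classical Barnes-maze scoring assigns each whole trial a single label:
*spatial* when the goal is found in fewer than 3 vestibule visits, *serial*
when the goal is reached through a run of at least 3 consecutive one-door
segments in one direction, and *random* otherwise.  It serves as the
comparison baseline for the stochastic-process estimates, which do not
assume one strategy per trial.

Edge conventions (the three verbal clauses leave them open): serial takes
precedence over spatial, and a non-serial trial of exactly 3 visits is
labelled random.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .maze import DEFAULT_MAZE, Dataset, MazeConfig, Trial
from .segmentation import segments_from_visits

__all__ = ["ClassifierConfig", "classify_trial", "classify_dataset", "LABELS"]

LABELS = ("spatial", "serial", "random")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the trial-wise classifier.

    ``spatial_max_visits`` is exclusive (< 3 visits -> spatial);
    ``serial_min_bout`` is the minimal length of the goal-terminating
    one-door run for a serial label.
    """

    spatial_max_visits: int = 3
    serial_min_bout: int = 3

    def __post_init__(self) -> None:
        if self.spatial_max_visits < 1 or self.serial_min_bout < 1:
            raise ValueError("classifier thresholds must be >= 1")


def classify_trial(trial: Trial, cfg: ClassifierConfig = ClassifierConfig(),
                   config: MazeConfig = DEFAULT_MAZE) -> str:
    """Label a complete trial as 'spatial', 'serial' or 'random'."""
    if not trial.is_complete(config):
        raise ValueError("classifier requires a complete (goal-ending) trial")
    segs = segments_from_visits(trial.start, trial.visits, config)
    # length of the direction-pure one-door run that ends at the goal
    tail = 0
    if segs and segs[-1] in (1, -1):
        last = segs[-1]
        for s in reversed(segs):
            if s == last:
                tail += 1
            else:
                break
    if tail >= cfg.serial_min_bout:
        return "serial"
    if len(segs) < cfg.spatial_max_visits:
        return "spatial"
    return "random"


def classify_dataset(dataset: Dataset,
                     cfg: ClassifierConfig = ClassifierConfig(),
                     config: MazeConfig = DEFAULT_MAZE) -> pd.DataFrame:
    """Per-day proportions of the three labels (rows sum to 1).

    Incomplete trials are skipped; days without a single complete trial are
    omitted.
    """
    rows = []
    for t in dataset:
        if t.is_complete(config):
            rows.append((t.day, classify_trial(t, cfg, config)))
    if not rows:
        raise ValueError("no complete trials to classify")
    df = pd.DataFrame(rows, columns=["day", "label"])
    out = (df.groupby("day")["label"]
             .value_counts(normalize=True)
             .unstack(fill_value=0.0)
             .reindex(columns=list(LABELS), fill_value=0.0))
    out.columns.name = None
    return out


def classify_to_frame(dataset: Dataset,
                      cfg: ClassifierConfig = ClassifierConfig(),
                      config: MazeConfig = DEFAULT_MAZE) -> pd.DataFrame:
    """Per-trial label table (mouse_id, day, trial, label)."""
    rows = [
        (t.mouse_id, t.day, t.trial, classify_trial(t, cfg, config))
        for t in dataset if t.is_complete(config)
    ]
    return pd.DataFrame(rows, columns=["mouse_id", "day", "trial", "label"])
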