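"""Normalised summary distributions of vestibule sequences and their MSE.

Four pooled distributions characterise a set of trials and define the
mixture-model fitting objective:

* trial length — number of segments per trial (1..``l_max``, overflow pooled
  into the top bin),
* vestibule visits — proportion of visits landing on each vestibule,
* segment size — signed door-steps, -12..-1 and +1..+12,
* serial bout length — lengths of maximal runs of same-direction one-door
  segments (1..``b_max``, overflow pooled).

The Markov-chain objective additionally resolves segment-size and vestibule
distributions by segment position within the trial (first ``K`` segments).
Model fits compare summaries through the mean of squared bin-wise
differences pooled over all bins with equal weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import DEFAULT_MAZE, Dataset, MazeConfig
from .simulate import SequenceBatch

__all__ = [
    "SummarySet",
    "PerIndexSummary",
    "summarize",
    "summarize_per_index",
    "serial_bouts",
    "mse",
]

logger = logging.getLogger(__name__)

DEFAULT_L_MAX = 30
DEFAULT_B_MAX = 15
DEFAULT_K = 10


def _normalize(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts / total if total > 0 else counts.astype(float)


@dataclass
class SummarySet:
    """The four pooled summary distributions of a trial set.

    Each component is a probability vector (sums to 1 whenever its sample
    count is positive).  ``segment_size`` is ordered -12..-1, +1..+12 (size
    0 cannot occur).
    """

    trial_length: np.ndarray
    vestibule_visits: np.ndarray
    segment_size: np.ndarray
    serial_bout: np.ndarray
    l_max: int = DEFAULT_L_MAX
    b_max: int = DEFAULT_B_MAX

    COMPONENTS = ("trial_length", "vestibule_visits", "segment_size",
                  "serial_bout")

    def as_vector(self, components: tuple[str, ...] | None = None
                  ) -> np.ndarray:
        components = components or self.COMPONENTS
        return np.concatenate([np.asarray(getattr(self, c), dtype=float)
                               for c in components])

    def segment_size_bins(self) -> np.ndarray:
        half = self.segment_size.size // 2
        return np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (component, bin, proportion) table."""
        rows = []
        for comp in self.COMPONENTS:
            vec = getattr(self, comp)
            if comp == "trial_length":
                bins = np.arange(1, self.l_max + 1)
            elif comp == "vestibule_visits":
                bins = np.arange(vec.size)
            elif comp == "segment_size":
                bins = self.segment_size_bins()
            else:
                bins = np.arange(1, self.b_max + 1)
            rows += [(comp, int(b), float(p)) for b, p in zip(bins, vec)]
        return pd.DataFrame(rows, columns=["component", "bin", "proportion"])


@dataclass
class PerIndexSummary:
    """Segment-position-resolved distributions for the first K segments.

    Row ``k`` of each array is the distribution over the k-th segment of all
    trials with at least k+1 segments; unpopulated rows are zero vectors.
    """

    segment_size_by_index: np.ndarray   # (K, 24)
    vestibule_by_index: np.ndarray      # (K, n_vestibules)
    k: int = DEFAULT_K

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.segment_size_by_index.ravel(),
                               self.vestibule_by_index.ravel()])


def serial_bouts(segment_sizes) -> list[int]:
    """Lengths of maximal runs of same-direction one-door segments.

    A bout is a maximal run of segments of size exactly +1, or exactly -1
    (a direction change breaks the run); isolated one-door segments count as
    bouts of length 1.
    """
    out: list[int] = []
    run_val = 0
    run_len = 0
    for s in list(segment_sizes) + [0]:
        if s == run_val and s in (1, -1):
            run_len += 1
            continue
        if run_val in (1, -1) and run_len:
            out.append(run_len)
        run_val, run_len = (s, 1) if s in (1, -1) else (0, 0)
    return out


def _batch_for(data, config: MazeConfig) -> SequenceBatch:
    if isinstance(data, SequenceBatch):
        return data
    complete = data.complete_trials(config)
    dropped = len(data.trials) - len(complete)
    if dropped:
        logger.info("summarize: excluded %d incomplete trial(s)", dropped)
    if not complete:
        raise ValueError("no complete trials to summarize")
    return SequenceBatch.from_dataset(complete)


def _bout_lengths_batch(seg: np.ndarray, mask: np.ndarray) -> np.ndarray:
    # flatten with a sentinel between trials so runs cannot bridge trials
    sent = 99
    padded = np.where(mask, seg, sent)
    flat = np.concatenate(
        [padded, np.full((padded.shape[0], 1), sent)], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    run_lens = np.diff(bounds)
    run_vals = flat[bounds[:-1]]
    return run_lens[(run_vals == 1) | (run_vals == -1)]


def summarize(data: Dataset | SequenceBatch,
              config: MazeConfig = DEFAULT_MAZE,
              l_max: int = DEFAULT_L_MAX,
              b_max: int = DEFAULT_B_MAX) -> SummarySet:
    """Pooled summary distributions over all complete trials.

    Incomplete (not goal-terminated or truncated) trials are excluded with a
    logged count; an empty input is an error.
    """
    batch = _batch_for(data, config)
    keep = ~batch.truncated
    if not keep.any():
        raise ValueError("no complete trials to summarize")
    lengths = batch.lengths[keep]
    visits = batch.visits[keep]
    seg = batch.segment_sizes(config)[keep]
    mask = batch.mask()[keep]

    tl = np.bincount(np.clip(lengths, 1, l_max), minlength=l_max + 1)[1:]
    vv = np.bincount(visits[mask], minlength=config.n_vestibules)
    half = config.max_span
    ss = np.bincount(seg[mask] + half, minlength=2 * half + 1)
    ss = np.delete(ss, half)  # size 0 cannot occur
    bouts = _bout_lengths_batch(seg, mask)
    sb = np.bincount(np.clip(bouts, 1, b_max), minlength=b_max + 1)[1:] \
        if bouts.size else np.zeros(b_max, dtype=np.int64)

    return SummarySet(_normalize(tl), _normalize(vv), _normalize(ss),
                      _normalize(sb), l_max=l_max, b_max=b_max)


def summarize_per_index(data: Dataset | SequenceBatch,
                        config: MazeConfig = DEFAULT_MAZE,
                        k: int = DEFAULT_K) -> PerIndexSummary:
    """Position-resolved summaries for the first ``k`` segments of each trial."""
    batch = _batch_for(data, config)
    keep = ~batch.truncated
    if not keep.any():
        raise ValueError("no complete trials to summarize")
    lengths = batch.lengths[keep]
    visits = batch.visits[keep]
    seg = batch.segment_sizes(config)[keep]
    half = config.max_span
    ss = np.zeros((k, 2 * half), dtype=float)
    vv = np.zeros((k, config.n_vestibules), dtype=float)
    L = visits.shape[1]
    for i in range(min(k, L)):
        m = lengths > i
        if not m.any():
            continue
        counts = np.bincount(seg[m, i] + half, minlength=2 * half + 1)
        ss[i] = _normalize(np.delete(counts, half))
        vv[i] = _normalize(
            np.bincount(visits[m, i], minlength=config.n_vestibules))
    return PerIndexSummary(ss, vv, k=k)


def _as_vector(obj) -> np.ndarray:
    if isinstance(obj, np.ndarray):
        return obj.ravel().astype(float)
    if isinstance(obj, (tuple, list)):
        return np.concatenate([_as_vector(o) for o in obj])
    if hasattr(obj, "as_vector"):
        return obj.as_vector()
    raise TypeError(f"cannot interpret {type(obj).__name__} as distributions")


def mse(a, b) -> float:
    """Mean squared bin-wise difference, pooled with equal bin weight.

    ``a`` and ``b`` may be :class:`SummarySet`, :class:`PerIndexSummary`,
    plain arrays, or tuples of these (concatenated); shapes must match.
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError("summary shapes do not match")
    return float(np.mean((va - vb) ** 2))
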