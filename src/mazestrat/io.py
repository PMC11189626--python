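"""CSV/JSON/YAML input-output and run configuration.

Sequence tables are long-format CSV with columns ``mouse_id, day, trial,
step_index, vestibule`` where step_index 0 is the start vestibule; fit
results are JSON carrying the estimates, the errors, the seed and a hash of
the producing configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maze import DEFAULT_MAZE, Dataset, MazeConfig
from .mixture import GridFitConfig, MixtureFitResult, MixtureParams
from .markov import GAConfig, GAResult, MarkovParams
from .strategies import SerialParams, SpatialParams, StrategyParams

__all__ = [
    "load_sequences",
    "save_sequences",
    "save_fit",
    "load_fit",
    "config_hash",
    "load_config",
]

logger = logging.getLogger(__name__)

SEQUENCE_COLUMNS = ["mouse_id", "day", "trial", "step_index", "vestibule"]


def load_sequences(path, config: MazeConfig = DEFAULT_MAZE) -> Dataset:
    """Read a sequence CSV into a validated :class:`Dataset`.

    Trials that do not end at the goal are kept but flagged incomplete (the
    summary layer excludes them with a logged count); malformed rows raise
    with the offending row named.
    """
    df = pd.read_csv(path)
    missing = set(SEQUENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["vestibule"] < 0)
                   | (df["vestibule"] >= config.n_vestibules)]
    if len(bad):
        raise ValueError(
            f"{path}: vestibule out of range 0..{config.n_vestibules - 1} "
            f"at row {int(bad[0]) + 2}")  # +2: header + 1-based
    ds = Dataset.from_dataframe(df)
    n_incomplete = sum(not t.is_complete(config) for t in ds)
    if n_incomplete:
        logger.info("%s: %d trial(s) do not end at the goal (flagged "
                    "incomplete)", path, n_incomplete)
    return ds


def save_sequences(dataset: Dataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    if isinstance(x, pd.Series):
        return {str(k): float(v) for k, v in x.items()}
    return x


def save_fit(result, path, *, seed=None, config: dict | None = None,
             include_surface: bool = True,
             surface_csv=None) -> None:
    """Serialise a mixture or GA fit result to JSON.

    Accepts a :class:`MixtureFitResult`/`MixtureResults` or a
    :class:`GAResult`/`MarkovResults`.  For mixture fits,
    ``surface_csv`` additionally writes the averaged error surface as a
    companion CSV (p_random, p_serial, p_spatial, mse).
    """
    inner = getattr(result, "_fit", result)
    payload: dict = {"seed": seed,
                     "config_hash": config_hash(config or {})}
    if isinstance(inner, MixtureFitResult):
        payload["kind"] = "mixture"
        payload["best"] = {
            "p_random": inner.best.p_random,
            "p_serial": inner.best.p_serial,
            "p_spatial": inner.best.p_spatial,
            "n_persist": inner.best.n_persist,
        }
        payload["min_mse"] = inner.min_mse
        if inner.error_by_n is not None:
            payload["error_by_n"] = _jsonify(inner.error_by_n)
        if include_surface:
            payload["error_surface"] = _jsonify(inner.error_surface)
        if surface_csv is not None:
            inner.error_surface.to_csv(surface_csv, index=False)
    elif isinstance(inner, GAResult):
        payload["kind"] = "markov"
        payload["best"] = {
            "initial": list(inner.best_matrix.initial),
            "transitions": [list(r) for r in inner.best_matrix.transitions],
        }
        payload["error_traces"] = _jsonify(inner.error_traces)
        payload["per_run_matrices"] = [
            _jsonify(p.matrix) for p in inner.per_run_matrices]
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration into typed parameter objects.

    Recognised blocks: ``maze`` (MazeConfig), ``strategies``
    (StrategyParams, keys spatial.tau, serial.center_cw, ...), ``grid``
    (GridFitConfig), ``ga`` (GAConfig).  Unknown blocks pass through
    untouched.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    out: dict = dict(raw)
    if "maze" in raw:
        out["maze"] = MazeConfig(**raw["maze"])
    if "strategies" in raw:
        s = raw["strategies"]
        out["strategies"] = StrategyParams(
            spatial=SpatialParams(**s.get("spatial", {})),
            serial=SerialParams(**s.get("serial", {})),
            max_steps_per_trial=s.get("max_steps_per_trial", 1000),
        )
    if "grid" in raw:
        g = dict(raw["grid"])
        if "n_range" in g:
            g["n_range"] = tuple(g["n_range"])
        if "objective" in g:
            g["objective"] = tuple(g["objective"])
        out["grid"] = GridFitConfig(**g)
    if "ga" in raw:
        out["ga"] = GAConfig(**raw["ga"])
    if "mixture_params" in raw:
        out["mixture_params"] = MixtureParams(**raw["mixture_params"])
    if "markov_params" in raw:
        m = raw["markov_params"]
        out["markov_params"] = MarkovParams(
            tuple(m["initial"]),
            tuple(tuple(r) for r in m["transitions"]))
    return out
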