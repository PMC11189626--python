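import numpy as np
import pytest

from mazestrat import (
    Dataset,
    MazeConfig,
    MixtureParams,
    Trial,
)
from mazestrat.synthetic import ExperimentPlan, generate_dataset, make_start_schedule


@pytest.fixture
def maze() -> MazeConfig:
    return MazeConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Three hand-written complete trials."""
    return Dataset([
        Trial("m1", 1, 1, start=22, visits=(23, 0)),
        Trial("m1", 1, 2, start=5, visits=(3, 0)),
        Trial("m2", 1, 1, start=2, visits=(1, 0)),
    ])


@pytest.fixture(scope="session")
def small_mixture_dataset():
    """190 trials generated from a known mixture parameterisation."""
    plan = ExperimentPlan(n_mice=19, days=1, trials_per_day=10,
                          params=MixtureParams(30.0, 30.0, 40.0, n_persist=6))
    rng = np.random.default_rng(777)
    sched = make_start_schedule(plan, rng)
    return generate_dataset(plan, rng, schedule=sched), sched
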