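"""Markov-chain simulator semantics and genetic-algorithm mechanics."""

import numpy as np
import pandas as pd
import pytest

from mazestrat import (
    GAConfig,
    MarkovParams,
    MarkovStrategyModel,
    crossover,
    ga_fit,
    mutate,
    normalize_rows,
    simulate_markov_dataset,
    simulate_markov_trial,
)
from mazestrat.simulate import simulate_markov_batch
from mazestrat.strategies import MARKOV_STRATEGIES


def schedule(n=60, seed=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "mouse_id": "m1", "day": 6, "trial": np.arange(1, n + 1),
        "start": rng.integers(2, 23, size=n),
    })


IDENTITY = MarkovParams((0.0, 0.0, 0.0, 1.0),
                        tuple(tuple(row) for row in np.eye(4)))


class TestSimulate:
    def test_absorbing_chain_keeps_one_label(self, rng):
        t = simulate_markov_trial(IDENTITY, 12, rng)
        assert set(t.strategy_labels) == {"spatial"}

    def test_serial_cw_absorbing_gives_positive_segments(self, rng):
        params = MarkovParams((0.0, 1.0, 0.0, 0.0),
                              tuple(tuple(row) for row in np.eye(4)))
        batch = simulate_markov_batch(
            np.array(params.initial), np.asarray(params.transitions),
            rng.integers(2, 23, 300), rng)
        seg = batch.segment_sizes()[batch.mask()]
        assert (seg >= 1).all()

    def test_label_transition_frequencies_match_matrix(self, rng):
        trans = np.array([
            [0.5, 0.2, 0.1, 0.2],
            [0.1, 0.6, 0.1, 0.2],
            [0.2, 0.1, 0.5, 0.2],
            [0.25, 0.25, 0.25, 0.25],
        ])
        batch = simulate_markov_batch(
            np.full(4, 0.25), trans, rng.integers(2, 23, 8000), rng)
        labs = batch.labels
        counts = np.zeros((4, 4))
        for i in range(batch.n_trials):
            k = batch.lengths[i]
            for a, b in zip(labs[i, : k - 1], labs[i, 1:k]):
                counts[a, b] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freq - trans).max() < 0.02

    def test_determinism(self):
        sched = schedule()
        params = MarkovParams((0.25, 0.25, 0.25, 0.25),
                              ((0.25,) * 4,) * 4)
        a = simulate_markov_dataset(params, sched, np.random.default_rng(3))
        b = simulate_markov_dataset(params, sched, np.random.default_rng(3))
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            MarkovParams((0.5, 0.5, 0.5, 0.5), ((0.25,) * 4,) * 4)


class TestOperators:
    def test_normalize_rows_examples(self):
        row = np.array([[0.5, 0.3, -0.1, 0.3]])
        out = normalize_rows(row)
        assert np.allclose(out, [[0.5 / 1.1, 0.3 / 1.1, 0.0, 0.3 / 1.1]])
        ok = np.array([[0.1, 0.2, 0.3, 0.4]])
        assert np.allclose(normalize_rows(ok), ok)
        assert np.allclose(normalize_rows(np.zeros((1, 4))), 0.25)

    def test_mutate_rows_stochastic_and_limit(self, rng):
        ind = np.random.default_rng(0).dirichlet(np.ones(4), size=5)
        out = mutate(ind, rng)
        assert np.allclose(out.sum(axis=1), 1.0)
        assert (out >= 0).all()
        tiny = mutate(ind, rng, GAConfig(mutation_half_range=1e-12))
        assert np.allclose(tiny, ind, atol=1e-9)

    def test_mutation_mean_absolute_change(self, rng):
        # uniform(-0.1, 0.1) noise has mean |change| 0.05 before renormalising
        deltas = np.abs(rng.uniform(-0.1, 0.1, size=100_000))
        assert abs(deltas.mean() - 0.05) < 0.002

    def test_crossover_rows_come_from_parents(self, rng):
        a = np.random.default_rng(1).dirichlet(np.ones(4), size=5)
        b = np.random.default_rng(2).dirichlet(np.ones(4), size=5)
        assert np.allclose(crossover(a, a, rng), a)
        picks = []
        for _ in range(300):
            child = crossover(a, b, rng)
            for i in range(5):
                from_a = np.allclose(child[i], a[i])
                assert from_a or np.allclose(child[i], b[i])
                picks.append(from_a)
        frac = np.mean(picks)
        sd = np.sqrt(0.25 / len(picks))
        assert abs(frac - 0.5) < 3 * sd


class TestGAFit:
    def test_elite_best_monotone_under_frozen_eval(self, small_mixture_dataset):
        ds, _ = small_mixture_dataset
        sched = schedule(50)
        cfg = GAConfig(population=12, generations=8, elite=6, repetitions=1,
                       frozen_eval=True)
        model = MarkovStrategyModel(ds.filter(days=[1]), schedule=sched)
        res = model.fit(cfg, seed=2)
        trace = res.error_trace
        assert (np.diff(trace) <= 1e-15).all()

    def test_every_individual_row_stochastic(self, rng):
        # mutation and crossover preserve row-stochasticity by construction
        pop = rng.dirichlet(np.ones(4), size=(10, 5))
        for _ in range(20):
            pop = np.array([mutate(ind, rng) for ind in pop])
            assert np.allclose(pop.sum(axis=2), 1.0)

    def test_repetitions_reported(self, small_mixture_dataset):
        ds, _ = small_mixture_dataset
        cfg = GAConfig(population=8, generations=3, elite=4, repetitions=2)
        res = ga_fit(ds, schedule(30), cfg, seed=5)
        assert res.error_traces.shape == (2, 3)
        assert len(res.per_run_matrices) == 2
        spread = res.matrix_spread()
        assert spread.shape == (5, 4)

    def test_summary_prints_matrix(self, small_mixture_dataset):
        ds, _ = small_mixture_dataset
        model = MarkovStrategyModel(ds)
        cfg = GAConfig(population=8, generations=3, elite=4, repetitions=1)
        res = model.fit(cfg, seed=1)
        text = res.summary()
        for name in MARKOV_STRATEGIES:
            assert name in text
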