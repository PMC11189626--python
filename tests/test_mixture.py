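"""Mixture model: simulation semantics and the grid-search estimator."""

import numpy as np
import pandas as pd
import pytest

from mazestrat import (
    GridFitConfig,
    MixtureModel,
    MixtureParams,
    fit_mixture_grid,
    simulate_mixture_dataset,
    simulate_mixture_trial,
    summarize,
)
from mazestrat.mixture import enumerate_simplex_grid
from mazestrat.simulate import simulate_mixture_batch


def small_schedule(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "mouse_id": "m1", "day": 1, "trial": np.arange(1, n + 1),
        "start": rng.integers(2, 23, size=n),
    })


class TestSimulateTrial:
    def test_pure_random_mean_length(self, rng):
        starts = rng.integers(1, 24, 10_000)
        batch = simulate_mixture_batch((100.0, 0.0, 0.0), 6, starts, rng)
        sem = batch.lengths.std(ddof=1) / np.sqrt(batch.lengths.size)
        assert abs(batch.lengths.mean() - 23.0) < 3 * sem

    def test_pure_spatial_first_visit_mode_is_goal(self, rng):
        starts = rng.integers(2, 23, 5_000)
        batch = simulate_mixture_batch((0.0, 0.0, 100.0), 6, starts, rng)
        first = batch.visits[:, 0]
        assert np.bincount(first, minlength=24).argmax() == 0

    def test_labels_change_only_at_block_boundaries(self, rng):
        params = MixtureParams(40.0, 30.0, 30.0, n_persist=4)
        for i in range(200):
            t = simulate_mixture_trial(params, 12, rng)
            labels = t.strategy_labels
            for j, lab in enumerate(labels):
                if j % 4 != 0:
                    assert lab == labels[j - 1]

    def test_n_persist_one_gives_independent_labels(self, rng):
        # lag-1 dependence of labels vanishes when every segment redraws
        params = MixtureParams(50.0, 25.0, 25.0, n_persist=1)
        pairs = []
        for _ in range(400):
            t = simulate_mixture_trial(params, 12, rng)
            labs = t.strategy_labels
            pairs += [(labs[j], labs[j + 1]) for j in range(len(labs) - 1)]
        pairs = np.array([(a == "random", b == "random") for a, b in pairs])
        p_joint = (pairs[:, 0] & pairs[:, 1]).mean()
        p_marg = pairs[:, 0].mean() * pairs[:, 1].mean()
        assert abs(p_joint - p_marg) < 0.03

    def test_scalar_and_batch_length_distributions_agree(self, rng):
        from scipy import stats

        params = MixtureParams(30.0, 30.0, 40.0, n_persist=6)
        scal = np.array([simulate_mixture_trial(params, 12, rng).n_segments
                         for _ in range(3000)])
        batch = simulate_mixture_batch(params.probs, 6, np.full(3000, 12),
                                       rng)
        ks = stats.ks_2samp(scal, batch.lengths)
        assert ks.pvalue > 0.001


class TestSimulateDataset:
    def test_schedule_shape_and_determinism(self):
        sched = small_schedule(190)
        params = MixtureParams(58.2, 28.4, 13.4, n_persist=6)
        a = simulate_mixture_dataset(params, sched,
                                     np.random.default_rng(4))
        b = simulate_mixture_dataset(params, sched,
                                     np.random.default_rng(4))
        assert len(a) == 190
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_empty_schedule_is_error(self):
        with pytest.raises(ValueError):
            simulate_mixture_dataset(
                MixtureParams(100.0, 0.0, 0.0), small_schedule(0),
                np.random.default_rng(0))


class TestGridFit:
    def test_simplex_enumeration_increment_50(self):
        pts = enumerate_simplex_grid(50)
        assert len(pts) == 6
        assert (pts.sum(axis=1) == 100).all()

    def test_invalid_increment(self):
        with pytest.raises(ValueError):
            enumerate_simplex_grid(3)

    def test_self_fit_attains_minimum_at_generating_point(self, rng):
        # target simulated at a coarse grid point; the fitted surface must
        # bottom out there when the schedule is reasonably large
        sched = small_schedule(400, seed=3)
        params = MixtureParams(50.0, 0.0, 50.0, n_persist=6)
        target = summarize(simulate_mixture_dataset(params, sched, rng))
        fit = fit_mixture_grid(target, sched,
                               GridFitConfig(increment=50, repetitions=5),
                               n_persist=6, seed=21)
        assert fit.best.p_random == 50.0
        assert fit.best.p_spatial == 50.0

    def test_recovery_error_shrinks_with_schedule_size(self, rng):
        # self-consistency: fitting a model-generated target gets closer to
        # the generating triple as the dataset grows
        truth = MixtureParams(40.0, 30.0, 30.0, n_persist=4)
        grid = GridFitConfig(increment=10, repetitions=3)
        errs = {}
        for n, seed in ((60, 61), (1000, 62)):
            sched = small_schedule(n, seed=seed)
            target = summarize(simulate_mixture_dataset(truth, sched, rng))
            fit = fit_mixture_grid(target, sched, grid, n_persist=4,
                                   seed=seed + 1)
            errs[n] = abs(fit.best.p_random - 40.0) + \
                abs(fit.best.p_serial - 30.0) + abs(fit.best.p_spatial - 30.0)
        assert errs[1000] <= errs[60] + 10.0
        assert errs[1000] <= 20.0

    def test_surface_reproducible_given_seed(self, tiny_dataset):
        sched = small_schedule(20)
        target = summarize(tiny_dataset)
        kw = dict(grid=GridFitConfig(increment=50, repetitions=2),
                  n_persist=2, seed=33)
        a = fit_mixture_grid(target, sched, **kw)
        b = fit_mixture_grid(target, sched, **kw)
        assert a.error_surface.equals(b.error_surface)

    def test_error_by_n_nonnegative_and_single_n(self, tiny_dataset):
        model = MixtureModel(tiny_dataset)
        res = model.fit_scan_n(
            GridFitConfig(increment=50, repetitions=2, n_range=(3,)),
            seed=5)
        assert res.params.n_persist == 3
        assert (res.error_by_n >= 0).all()

    def test_results_summary_mentions_estimates(self, tiny_dataset):
        model = MixtureModel(tiny_dataset)
        res = model.fit(n_persist=2,
                        grid=GridFitConfig(increment=50, repetitions=2),
                        seed=1)
        text = res.summary()
        assert "random" in text and "persistence N" in text
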