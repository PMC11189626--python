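"""Distributional and structural checks of the three stochastic processes."""

import numpy as np
import pytest
from scipy import stats

from mazestrat import (
    SerialParams,
    SpatialParams,
    StrategyParams,
    draw_random_step,
    draw_serial_step,
    draw_spatial_step,
    run_process_until_goal,
    spatial_weights,
)
from mazestrat.maze import MazeConfig, circular_distance
from mazestrat.simulate import (
    _batch_random,
    _batch_serial,
    _spatial_cum,
    simulate_process_batch,
)


def serial_step_pmf(center: float, sd: float, sign: int,
                    support: np.ndarray) -> np.ndarray:
    """Exact pmf of the rounded, sign-truncated normal serial step."""
    p = stats.norm.cdf((support + 0.5 - center) / sd) - \
        stats.norm.cdf((support - 0.5 - center) / sd)
    p = np.where(np.sign(support) == sign, p, 0.0)
    return p / p.sum()


class TestRandomStep:
    def test_never_returns_current_and_uniform(self, rng):
        draws = np.array([draw_random_step(5, rng) for _ in range(100_000)])
        assert (draws != 5).all()
        counts = np.bincount(draws, minlength=24)
        assert counts[5] == 0
        chi = stats.chisquare(np.delete(counts, 5))
        assert chi.pvalue > 0.001

    def test_deterministic_given_seed(self):
        a = [draw_random_step(3, np.random.default_rng(9)) for _ in range(50)]
        b = [draw_random_step(3, np.random.default_rng(9)) for _ in range(50)]
        assert a == b

    def test_batch_matches_scalar_distribution(self, rng):
        cur = np.full(100_000, 17)
        draws = _batch_random(rng, cur, 24)
        assert (draws != 17).all()
        chi = stats.chisquare(np.delete(np.bincount(draws, minlength=24), 17))
        assert chi.pvalue > 0.001


class TestSpatialStep:
    def test_weights_closed_form(self):
        w = spatial_weights(params=SpatialParams(tau=2.0))
        assert w[0] == pytest.approx(1.0)
        assert w[2] == pytest.approx(np.exp(-1.0))
        for v in range(1, 12):
            assert w[v] == pytest.approx(w[24 - v])
        assert w.argmax() == 0

    @pytest.mark.parametrize("current", [1, 5, 12, 23])
    def test_batch_cum_matches_enumeration_oracle(self, current):
        # explicit renormalisation over the 23 allowed vestibules
        cfg = MazeConfig()
        d = np.array([circular_distance(v, 0) for v in range(24)])
        w = np.exp(-d / 2.0)
        w[current] = 0.0
        oracle = np.cumsum(w / w.sum())
        got = _spatial_cum(cfg, 2.0)[current]
        assert np.allclose(got[:-1], oracle[:-1], atol=1e-12)

    def test_draw_frequencies_match_renormalised_exponential(self, rng):
        current = 7
        d = np.array([circular_distance(v, 0) for v in range(24)])
        w = np.exp(-d / 2.0)
        w[current] = 0.0
        expected = w / w.sum()
        draws = np.array([draw_spatial_step(current, rng)
                          for _ in range(20_000)])
        assert (draws != current).all()
        counts = np.bincount(draws, minlength=24)
        chi = stats.chisquare(np.delete(counts, current),
                              20_000 * np.delete(expected, current))
        assert chi.pvalue > 0.001
        # goal is the single most likely outcome
        assert counts.argmax() == 0


class TestSerialStep:
    def test_unified_sign_bias(self, rng):
        signs = []
        for _ in range(10_000):
            _, s = draw_serial_step(10, rng, direction="unified")
            signs.append(s > 0)
        frac = np.mean(signs)
        sd = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac - 0.8) < 3 * sd

    def test_cw_mode_all_steps_positive(self, rng):
        steps = [draw_serial_step(10, rng, direction="cw")[1]
                 for _ in range(2_000)]
        assert min(steps) >= 1

    def test_cw_step_distribution_matches_truncated_normal_oracle(self, rng):
        n = 100_000
        support = np.arange(1, 13)
        pmf = serial_step_pmf(1.2, 1.2, 1, support)
        cur = np.full(n, 10)
        nxt = _batch_serial(rng, cur, np.ones(n, dtype=int),
                            SerialParams(), 24)
        steps = (nxt - 10) % 24
        counts = np.bincount(steps, minlength=13)[1:]
        # pool the far tail, where expected counts are < 5, into one bin
        cut = np.searchsorted(np.cumsum(n * pmf < 5), 1)
        obs = np.append(counts[:cut], counts[cut:].sum())
        exp = np.append(n * pmf[:cut], n * pmf[cut:].sum())
        chi = stats.chisquare(obs, exp)
        assert chi.pvalue > 0.001

    def test_ccw_scalar_matches_oracle(self, rng):
        support = np.arange(-12, 0)
        pmf = serial_step_pmf(-2.0, 1.5, -1, support)
        steps = np.array([draw_serial_step(10, rng, direction="ccw")[1]
                          for _ in range(20_000)])
        counts = np.bincount(steps + 12, minlength=13)[:12]
        chi = stats.chisquare(counts, 20_000 * pmf)
        assert chi.pvalue > 0.001


class TestRunProcess:
    def test_random_mean_trial_length_is_geometric(self, rng):
        # success probability 1/23 per draw -> mean 23
        starts = rng.integers(1, 24, size=10_000)
        batch = simulate_process_batch("random", starts, rng)
        assert not batch.truncated.any()
        mean = batch.lengths.mean()
        sem = batch.lengths.std(ddof=1) / np.sqrt(batch.lengths.size)
        assert abs(mean - 23.0) < 3 * sem

    def test_spatial_always_terminates(self, rng):
        params = StrategyParams(max_steps_per_trial=10_000)
        starts = rng.integers(1, 24, size=10_000)
        batch = simulate_process_batch("spatial", starts, rng, params=params)
        assert batch.truncated.sum() == 0

    def test_start_at_goal_gives_zero_segments(self, rng):
        t = run_process_until_goal("random", 0, rng)
        assert t.n_segments == 0 and t.is_complete()

    def test_no_segment_is_zero_for_any_process(self, rng):
        for proc in ("random", "serial", "spatial"):
            batch = simulate_process_batch(proc, rng.integers(1, 24, 500), rng)
            seg = batch.segment_sizes()[batch.mask()]
            assert ((np.abs(seg) >= 1) & (np.abs(seg) <= 12)).all()

    def test_strict_mode_raises_on_guard(self, rng):
        params = StrategyParams(max_steps_per_trial=1)
        with pytest.raises(RuntimeError):
            for _ in range(200):
                run_process_until_goal("random", 12, rng, params=params,
                                       strict=True)

    def test_labels_attached(self, rng):
        t = run_process_until_goal("serial", 12, rng)
        assert t.strategy_labels == ("serial",) * t.n_segments
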