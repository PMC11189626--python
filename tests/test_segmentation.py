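"""Trajectory segmentation: threshold crossings, path length, bouts."""

import numpy as np
import pytest

from mazestrat import (
    MazeConfig,
    Trial,
    compute_path_length,
    detect_vestibule_visits,
    segments_from_visits,
    serial_bouts,
    visit_sequence,
)
from mazestrat.segmentation import XYTrajectory
from mazestrat.simulate import simulate_mixture_batch
from mazestrat.synthetic import synthesize_xy_trajectory


def straight_traj(points, rate=25.0):
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) / rate
    return XYTrajectory("m", 1, 1, t, pts[:, 0], pts[:, 1])


class TestDetectVisits:
    def test_radius_threshold(self, maze):
        # 48 cm is inside a vestibule zone, 47 cm is arena
        traj = straight_traj([(0, 47.0), (0, 48.0), (0, 47.0)])
        events = detect_vestibule_visits(traj, maze)
        assert len(events) == 1
        assert events[0].vestibule == 0  # goal sits at the top
        assert events[0].t_enter < events[0].t_exit

    def test_no_crossing_gives_no_events(self, maze):
        traj = straight_traj([(0, 0), (10, 10), (-5, 3)])
        assert detect_vestibule_visits(traj, maze) == []

    def test_empty_trajectory_is_error(self, maze):
        with pytest.raises(ValueError):
            detect_vestibule_visits(straight_traj(np.empty((0, 2))), maze)

    def test_entirely_outside_is_single_visit(self, maze):
        traj = straight_traj([(0, 50.0), (0, 51.0), (0.5, 50.0)])
        events = detect_vestibule_visits(traj, maze)
        assert len(events) == 1

    def test_round_trip_recovers_scripted_sequences(self, maze, rng):
        starts = rng.integers(1, 24, size=150)
        batch = simulate_mixture_batch((34.0, 33.0, 33.0), 6, starts, rng)
        for trial in batch.to_trials():
            traj = synthesize_xy_trajectory(trial, maze, rng)
            events = detect_vestibule_visits(traj, maze)
            seq = visit_sequence(events)
            assert seq[0] == trial.start
            assert tuple(seq[1:]) == trial.visits


class TestPathLengthBySegmentSize:
    def test_segments_paired_with_lengths(self, maze, rng):
        from mazestrat.segmentation import path_length_by_segment_size
        from mazestrat import Trial

        trial = Trial("m", 1, 1, 6, (3, 4, 0))
        traj = synthesize_xy_trajectory(trial, maze, rng)
        df = path_length_by_segment_size(traj, maze)
        assert df["segment_size"].tolist() == [-3, 1, -4]
        # longer spans cover more arc
        assert df["path_length_cm"].iloc[2] > df["path_length_cm"].iloc[1]


class TestPathLength:
    def test_345_triangle(self):
        assert compute_path_length([0, 3], [0, 4]) == pytest.approx(5.0)

    def test_additivity_on_straight_line(self):
        x = np.linspace(0, 10, 11)
        assert compute_path_length(x, np.zeros_like(x)) == pytest.approx(10.0)

    def test_single_sample_is_zero(self):
        assert compute_path_length([1.0], [2.0]) == 0.0

    def test_arc_matches_analytic_length(self):
        # quarter circle of radius 40 sampled at < 2 degree steps
        theta = np.linspace(0, np.pi / 2, 200)
        x, y = 40 * np.cos(theta), 40 * np.sin(theta)
        assert compute_path_length(x, y) == pytest.approx(
            40 * np.pi / 2, rel=0.01)


class TestSegments:
    def test_examples(self):
        assert segments_from_visits(5, [3, 0]) == [-2, -3]
        assert segments_from_visits(22, [23, 0]) == [1, 1]

    def test_sizes_in_legal_range(self, rng):
        for _ in range(100):
            seq = [int(rng.integers(0, 24))]
            for _ in range(10):
                nxt = int(rng.integers(0, 24))
                if nxt != seq[-1]:
                    seq.append(nxt)
            segs = segments_from_visits(seq[0], seq[1:])
            assert all(1 <= abs(s) <= 12 for s in segs)

    def test_zero_size_segment_is_error(self):
        with pytest.raises(ValueError):
            segments_from_visits(5, [5, 0])


class TestSerialBouts:
    @pytest.mark.parametrize("segs,expected", [
        ([1, 1, 1, -3, 1, 1], [3, 2]),
        ([2, -4, 6], []),
        ([1, -1, 1], [1, 1, 1]),   # direction change breaks the run
        ([], []),
        ([-1, -1], [2]),
    ])
    def test_examples(self, segs, expected):
        assert serial_bouts(segs) == expected

    def test_total_bout_mass_counts_unit_segments(self, rng):
        segs = [int(s) for s in rng.integers(-3, 4, size=500) if s != 0]
        assert sum(serial_bouts(segs)) == \
            sum(1 for s in segs if abs(s) == 1)
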