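"""Rapid-motion gating, transition costs, exact min-cost-flow linking."""

import math

import numpy as np
import pytest

from conftest import brute_force_cover_cost, point_detection, random_track_instance
from opctrack.config import MotionParams, SimConfig
from opctrack.errors import ContractViolation
from opctrack.movie import Movie
from opctrack.simulate import simulate_movie
from opctrack.track import (
    NORMAL,
    RAPID,
    TrackGraph,
    build_track_graph,
    rapid_motion_flags,
    solve_tracks,
    transition_cost,
    track_movie,
)


class TestRapidFlags:
    def test_static_noise_free_scene_never_flags(self):
        cfg = SimConfig(
            n_frames=6, n_dorsal_migratory=0, n_ventral_migratory=0,
            noise_sd=0.0, jitter_sd_px=0.0, bleach_rate_per_frame=0.0, seed=1,
        )
        movie, gt = simulate_movie(cfg)
        dets = [[point_detection(t, *gt.positions[i, t]) for i in range(gt.n_cells)]
                for t in range(cfg.n_frames)]
        flags = rapid_motion_flags(movie, dets)
        assert not any(f.any() for f in flags)

    def test_disappearing_cell_flagged(self):
        """A jump beyond the window empties it between t and t+1."""
        rng = np.random.default_rng(0)
        base = 100 + rng.normal(0, 5, (3, 64, 64))
        from opctrack.simulate import _render_frame

        _render_frame(base[0], np.array([[20.0, 20.0]]), 1000.0, 2.0)
        _render_frame(base[1], np.array([[45.0, 45.0]]), 1000.0, 2.0)
        _render_frame(base[2], np.array([[45.0, 45.0]]), 1000.0, 2.0)
        movie = Movie(base)
        dets = [[point_detection(0, 20, 20)], [point_detection(1, 45, 45)], []]
        flags = rapid_motion_flags(movie, dets, window_px=6, z_threshold=3.0)
        assert flags[0][0]  # its neighbourhood lost the cell

    def test_noise_null_flag_rate_below_one_percent(self):
        rng = np.random.default_rng(3)
        movie = Movie(100 + rng.normal(0, 20, (101, 64, 64)))
        dets = [
            [point_detection(t, *rng.uniform(10, 54, 2)) for _ in range(10)]
            for t in range(100)
        ] + [[]]
        flags = rapid_motion_flags(movie, dets, window_px=6, z_threshold=3.0)
        rate = np.mean(np.concatenate([f for f in flags if len(f)]))
        assert rate <= 0.01


class TestTransitionCost:
    motion = MotionParams()

    def test_zero_displacement_is_mode_minimum(self):
        d0, d1 = point_detection(0, 5, 5), point_detection(1, 5, 5)
        c0 = transition_cost(d0, d1, NORMAL, self.motion)
        far = point_detection(1, 6.5, 5)
        assert c0 < transition_cost(d0, far, NORMAL, self.motion)

    def test_gaussian_log_density_difference(self):
        s = self.motion.sigma_normal_px
        d0 = point_detection(0, 0, 0)
        at_sigma = point_detection(1, s, 0)
        at_two_sigma = point_detection(1, 2 * s, 0)
        diff = transition_cost(d0, at_two_sigma, NORMAL, self.motion) - transition_cost(
            d0, at_sigma, NORMAL, self.motion
        )
        assert diff == pytest.approx(1.5)

    def test_large_jump_cheaper_in_rapid_mode(self):
        motion = MotionParams(sigma_normal_px=2.0, sigma_rapid_px=8.0)
        d0, d1 = point_detection(0, 0, 0), point_detection(1, 12, 0)
        c_norm = transition_cost(d0, d1, NORMAL, motion, apply_cutoff=False)
        c_rapid = transition_cost(d0, d1, RAPID, motion, apply_cutoff=False)
        assert c_rapid < c_norm

    def test_beyond_cutoff_is_infinite(self):
        d0, d1 = point_detection(0, 0, 0), point_detection(1, 50, 0)
        assert transition_cost(d0, d1, NORMAL, self.motion) == math.inf

    def test_backward_pair_rejected(self):
        with pytest.raises(ContractViolation):
            transition_cost(point_detection(1, 0, 0), point_detection(0, 0, 0), NORMAL, self.motion)


class TestSolver:
    def test_single_chain_of_detections(self):
        dets = [[point_detection(t, 10 + 0.3 * t, 10)] for t in range(6)]
        motion = MotionParams(p_birth=0.01, p_det=0.99)
        sol = solve_tracks(build_track_graph(dets, motion))
        assert len(sol.tracks) == 1
        assert len(sol.tracks[0].entries) == 6

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            graph = random_track_instance(rng)
            sol = solve_tracks(graph)
            assert sol.total_cost == pytest.approx(brute_force_cover_cost(graph), abs=1e-9)

    def test_node_disjointness(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            graph = random_track_instance(rng)
            sol = solve_tracks(graph)
            seen = set()
            for tr in sol.tracks:
                for _, det in tr.entries:
                    assert id(det) not in seen
                    seen.add(id(det))

    def test_crossing_cells_resolved_like_the_oracle(self):
        """Identity preservation through a crossing iff it is the cheaper cover."""
        # two cells cross in y but stay in separate x lanes, so swapping
        # identities at the crossing would cost an extra lateral jump
        dets = []
        for t in range(4):
            dets.append([
                point_detection(t, 10 + 2.0 * t, 8),    # moving down, lane x=8
                point_detection(t, 16 - 2.0 * t, 12),   # moving up, lane x=12
            ])
        motion = MotionParams(sigma_normal_px=1.5, p_birth=0.05, p_det=0.99)
        graph = build_track_graph(dets, motion)
        sol = solve_tracks(graph)
        assert sol.total_cost == pytest.approx(brute_force_cover_cost(graph), abs=1e-9)
        assert len(sol.tracks) == 2
        for tr in sol.tracks:
            assert len(tr.entries) == 4
            assert np.ptp(tr.positions[:, 1]) == 0.0  # stayed in its lane

    def test_birth_cost_monotonicity(self):
        """Raising all entry costs never increases the number of tracks."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            graph = random_track_instance(rng)
            n0 = len(solve_tracks(graph).tracks)
            bumped = TrackGraph(
                detections=graph.detections,
                entry_cost=graph.entry_cost + 1.0,
                exit_cost=graph.exit_cost,
                det_cost=graph.det_cost,
                transitions=graph.transitions,
            )
            assert len(solve_tracks(bumped).tracks) <= n0


def test_link_recovery_on_synthetic_movie():
    """>= 95% of consecutive links match ground truth at moderate noise."""
    cfg = SimConfig(n_stationary=15, n_dorsal_migratory=5, n_ventral_migratory=0, seed=21)
    movie, gt = simulate_movie(cfg)
    from opctrack.config import DetectParams
    from opctrack.detect import detect_movie
    from opctrack.preprocess import correct_photobleach

    corrected = correct_photobleach(movie)
    dets = detect_movie(corrected.data, DetectParams())
    sol = track_movie(corrected, dets, MotionParams())
    good = total = 0
    for tr in sol.tracks:
        frames, pos = tr.frames, tr.positions
        if len(frames) < 2:
            continue
        errs = [np.nanmean(np.hypot(*(pos - gt.positions[i, frames]).T)) for i in range(gt.n_cells)]
        cell = int(np.nanargmin(errs))
        for k in range(len(frames) - 1):
            total += 1
            ok = (
                np.hypot(*(pos[k] - gt.positions[cell, frames[k]])) < 2.0
                and np.hypot(*(pos[k + 1] - gt.positions[cell, frames[k + 1]])) < 2.0
            )
            good += ok
    assert total > 0
    assert good / total >= 0.95
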