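"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from opctrack.config import SimConfig
from opctrack.detect import Detection
from opctrack.simulate import _render_frame


@pytest.fixture
def clean_sim_config():
    """Noise-free, bleach-free, drift-free scene with a handful of cells."""
    return SimConfig(
        n_frames=20,
        n_stationary=5,
        n_dorsal_migratory=1,
        n_ventral_migratory=1,
        noise_sd=0.0,
        jitter_sd_px=0.0,
        bleach_rate_per_frame=0.0,
        seed=123,
    )


def make_blob_frame(
    centers, shape=(100, 100), amplitude=1000.0, sigma=2.0, background=100.0, noise_sd=0.0, seed=0
):
    """A frame of Gaussian blobs at known subpixel centres."""
    frame = np.full(shape, float(background))
    _render_frame(frame, np.atleast_2d(np.asarray(centers, dtype=float)), amplitude, sigma)
    if noise_sd > 0:
        frame += np.random.default_rng(seed).normal(0, noise_sd, shape)
    return frame


def point_detection(frame: int, y: float, x: float) -> Detection:
    """A minimal single-pixel detection for solver/cost tests."""
    return Detection(
        frame=frame,
        centroid=np.array([y, x], dtype=float),
        pixels=np.array([[int(round(y)), int(round(x))]], dtype=int),
    )


def brute_force_cover_cost(graph) -> float:
    """Exhaustive minimum cost over all node-disjoint path covers.

    Independent oracle for the flow solver: every detection may be
    skipped, start a new track, or extend an existing track end along a
    finite transition arc; a track pays entry + exit + its detections'
    costs + its transitions.  Exponential, so only for tiny instances.
    """
    n = len(graph.detections)
    edge: dict[tuple[int, int], float] = {}
    for i, j, c, _mode in graph.transitions:
        edge[(i, j)] = min(edge.get((i, j), math.inf), c)
    best = [0.0]  # the empty cover is always feasible

    def rec(i: int, open_ends: tuple[int, ...], cost: float) -> None:
        if i == n:
            total = cost + sum(graph.exit_cost[e] for e in open_ends)
            if total < best[0]:
                best[0] = total
            return
        rec(i + 1, open_ends, cost)  # skip detection i
        rec(i + 1, open_ends + (i,), cost + graph.entry_cost[i] + graph.det_cost[i])
        for k, e in enumerate(open_ends):
            if (e, i) in edge:
                rec(
                    i + 1,
                    open_ends[:k] + open_ends[k + 1 :] + (i,),
                    cost + edge[(e, i)] + graph.det_cost[i],
                )

    rec(0, (), 0.0)
    return best[0]


def random_track_instance(rng: np.random.Generator):
    """Small random linking instance (<= 3 detections/frame, <= 4 frames)."""
    from opctrack.track import TrackGraph

    n_frames = int(rng.integers(2, 5))
    dets = []
    for t in range(n_frames):
        for _ in range(int(rng.integers(0, 4))):
            dets.append(point_detection(t, *rng.uniform(0, 10, 2)))
    n = len(dets)
    transitions = []
    for i in range(n):
        for j in range(n):
            gap = dets[j].frame - dets[i].frame
            if 1 <= gap <= 2 and rng.random() < 0.8:
                transitions.append((i, j, float(rng.uniform(-1.0, 2.0)), "normal"))
    return TrackGraph(
        detections=dets,
        entry_cost=rng.uniform(0.5, 3.0, n),
        exit_cost=rng.uniform(0.5, 3.0, n),
        det_cost=rng.uniform(-4.0, 0.0, n),
        transitions=transitions,
    )


def match_track_to_cell(track, ground_truth) -> int:
    """Index of the ground-truth cell closest (mean same-frame distance) to a track."""
    frames, pos = track.frames, track.positions
    errs = [
        np.nanmean(np.hypot(*(pos - ground_truth.positions[i, frames]).T))
        for i in range(ground_truth.n_cells)
    ]
    return int(np.nanargmin(errs))
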