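"""Min-cost-flow linking of detections into trajectories.

Data association is posed as a node-disjoint path cover on a DAG: every
detection is a split node pair (capacity one) carrying a confidence
reward, entry/exit arcs carry birth/death costs, and transition arcs
carry the negative log-density of the displacement under a mixed motion
model — an isotropic Gaussian with SD ``sigma_normal_px`` per unit
frame gap for ordinary motion, or the wider ``sigma_rapid_px`` regime
for arcs whose endpoints were flagged by the regional
intensity-change test.  The global optimum is found exactly by
successive shortest paths on the residual graph with potential-based
cost reduction; augmentation stops when no negative-cost track remains.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import MotionParams
from .detect import Detection
from .errors import ConfigurationError, ContractViolation
from .movie import Movie

logger = logging.getLogger(__name__)

NORMAL = "normal"
RAPID = "rapid"


# ---------------------------------------------------------------------------
# rapid-motion gating


def rapid_motion_flags(
    movie: Movie,
    detections: list[list[Detection]],
    window_px: int = 6,
    z_threshold: float = 3.0,
) -> list[np.ndarray]:
    """Flag detections whose neighbourhood intensity changes abruptly.

    For a detection in frame ``t`` the mean of the frame difference
    ``t -> t+1`` inside a square window of half-width ``window_px`` is
    standardized against the whole-difference-frame distribution (robust
    median/MAD scale, with a ``sqrt(n)`` factor for the window mean).
    ``|z| > z_threshold`` flags the detection; flagged endpoints unlock
    rapid-motion transition arcs.  Detections in the final frame (no
    forward difference) are never flagged.
    """
    if window_px < 1:
        raise ConfigurationError("window_px must be >= 1")
    T, H, W = movie.shape
    flags: list[np.ndarray] = []
    for t, dets in enumerate(detections):
        f = np.zeros(len(dets), dtype=bool)
        if t + 1 < T and dets:
            diff = movie.data[t + 1] - movie.data[t]
            med = float(np.median(diff))
            mad = float(np.median(np.abs(diff - med)))
            sigma = 1.4826 * mad
            if sigma > 0:
                for i, det in enumerate(dets):
                    cy, cx = (int(round(v)) for v in det.centroid)
                    y0, y1 = max(cy - window_px, 0), min(cy + window_px + 1, H)
                    x0, x1 = max(cx - window_px, 0), min(cx + window_px + 1, W)
                    if y0 >= y1 or x0 >= x1:
                        logger.warning(
                            "frame %d: rapid-motion window fully outside field for detection %d", t, i
                        )
                        continue
                    win = diff[y0:y1, x0:x1]
                    z = (win.mean() - med) * math.sqrt(win.size) / sigma
                    f[i] = abs(z) > z_threshold
        flags.append(f)
    return flags


# ---------------------------------------------------------------------------
# costs and graph


def transition_cost(
    d1: Detection,
    d2: Detection,
    mode: str,
    motion: MotionParams,
    apply_cutoff: bool = True,
) -> float:
    """Negative log displacement density for linking two detections.

    The density is isotropic Gaussian with per-axis SD
    ``sigma_mode * sqrt(gap)``; skipped frames add ``gap_penalty`` each.
    Returns ``inf`` beyond the mode's distance cutoff or the maximum
    gap.
    """
    gap = d2.frame - d1.frame
    if gap < 1:
        raise ContractViolation("transition must go forward in time")
    if gap > motion.max_gap_frames:
        return math.inf
    sigma = motion.sigma_normal_px if mode == NORMAL else motion.sigma_rapid_px
    sd = sigma * math.sqrt(gap)
    dist = float(np.hypot(*(d2.centroid - d1.centroid)))
    if apply_cutoff and dist > motion.cutoff_sigmas * sd:
        return math.inf
    return dist**2 / (2.0 * sd**2) + math.log(2.0 * math.pi * sd**2) + motion.gap_penalty * (gap - 1)


@dataclass
class TrackGraph:
    """Flow network over detections: split nodes, entry/exit/transition arcs."""

    detections: list[Detection]                  # topologically ordered by (frame, index)
    entry_cost: np.ndarray                       # (n,) cost source -> detection
    exit_cost: np.ndarray                        # (n,) cost detection -> sink
    det_cost: np.ndarray                         # (n,) cost of using the detection (reward if < 0)
    transitions: list[tuple[int, int, float, str]] = field(default_factory=list)
    # (i, j, cost, mode) with frame(j) > frame(i)

    def __post_init__(self):
        for i, j, _, _ in self.transitions:
            if self.detections[j].frame <= self.detections[i].frame:
                raise ContractViolation("transition arcs must move forward in time")


def build_track_graph(
    detections: list[list[Detection]],
    motion: MotionParams,
    rapid_flags: list[np.ndarray] | None = None,
) -> TrackGraph:
    """Assemble the linking network from per-frame detections."""
    flat: list[Detection] = []
    index: list[list[int]] = []
    for t, dets in enumerate(detections):
        idx = []
        for d in dets:
            idx.append(len(flat))
            flat.append(d)
        index.append(idx)
    n = len(flat)
    entry = np.full(n, -math.log(motion.p_birth))
    exit_ = np.full(n, -math.log(motion.p_birth))
    det_cost = np.full(n, math.log((1.0 - motion.p_det) / motion.p_det))

    if rapid_flags is None:
        rapid_flags = [np.zeros(len(dets), dtype=bool) for dets in detections]

    transitions: list[tuple[int, int, float, str]] = []
    for t, dets in enumerate(detections):
        for dt in range(1, motion.max_gap_frames + 1):
            if t + dt >= len(detections):
                break
            for a, da in enumerate(dets):
                for b, db in enumerate(detections[t + dt]):
                    c_norm = transition_cost(da, db, NORMAL, motion)
                    rapid_ok = rapid_flags[t][a] or rapid_flags[t + dt][b]
                    c_rapid = transition_cost(da, db, RAPID, motion) if rapid_ok else math.inf
                    if c_rapid < c_norm:
                        cost, mode = c_rapid, RAPID
                    else:
                        cost, mode = c_norm, NORMAL
                    if math.isfinite(cost):
                        transitions.append((index[t][a], index[t + dt][b], cost, mode))
    return TrackGraph(flat, entry, exit_, det_cost, transitions)


# ---------------------------------------------------------------------------
# exact solver


@dataclass
class Track:
    """One linked trajectory."""

    track_id: int
    entries: list[tuple[int, Detection]]          # time-ordered (frame, detection)
    is_rapid: list[bool] = field(default_factory=list)  # per link

    @property
    def frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.entries], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.centroid for _, d in self.entries], dtype=float)


@dataclass
class TrackSolution:
    tracks: list[Track]
    total_cost: float


def solve_tracks(graph: TrackGraph) -> TrackSolution:
    """Exact min-cost node-disjoint path cover by successive shortest paths.

    Augments one unit of flow along the cheapest residual source-sink
    path while that path has negative total cost; with unit node
    capacities this yields the globally optimal set of tracks.  Shortest
    paths are found by a label-correcting search, which is robust to the
    negative arc costs of detection rewards and residual arcs (the
    residual graph of a successive-shortest-path flow never contains a
    negative cycle).  Ties are broken deterministically by node index.
    """
    n = len(graph.detections)
    S, T = 0, 1
    n_nodes = 2 + 2 * n

    def nin(i):
        return 2 + 2 * i

    def nout(i):
        return 3 + 2 * i

    arcs: list[list[float]] = []  # [u, v, cost, flow]
    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    modes: dict[int, str] = {}

    def add_arc(u, v, cost, mode=None):
        aid = len(arcs)
        arcs.append([u, v, float(cost), 0])
        adj[u].append(aid)
        if mode is not None:
            modes[aid] = mode
        return aid

    for i in range(n):
        add_arc(S, nin(i), graph.entry_cost[i])
        add_arc(nin(i), nout(i), graph.det_cost[i])
        add_arc(nout(i), T, graph.exit_cost[i])
    for i, j, cost, mode in graph.transitions:
        add_arc(nout(i), nin(j), cost, mode)

    radj: list[list[int]] = [[] for _ in range(n_nodes)]

    total_cost = 0.0
    while True:
        dist = np.full(n_nodes, np.inf)
        prev_arc = np.full(n_nodes, -1, dtype=int)
        prev_dir = np.zeros(n_nodes, dtype=int)  # +1 forward, -1 backward
        for lst in radj:
            lst.clear()
        for aid, (u, v, _c, flow) in enumerate(arcs):
            if flow > 0:
                radj[v].append(aid)
        dist[S] = 0.0
        in_queue = np.zeros(n_nodes, dtype=bool)
        queue = deque([S])
        in_queue[S] = True
        while queue:
            u = queue.popleft()
            in_queue[u] = False
            du = dist[u]
            for aid in adj[u]:
                _, v, cost, flow = arcs[aid]
                if flow < 1 and du + cost < dist[v] - 1e-12:
                    dist[v] = du + cost
                    prev_arc[v] = aid
                    prev_dir[v] = 1
                    if not in_queue[v]:
                        queue.append(v)
                        in_queue[v] = True
            for aid in radj[u]:
                w = arcs[aid][0]
                cost = arcs[aid][2]
                if du - cost < dist[w] - 1e-12:
                    dist[w] = du - cost
                    prev_arc[w] = aid
                    prev_dir[w] = -1
                    if not in_queue[w]:
                        queue.append(w)
                        in_queue[w] = True

        if not np.isfinite(dist[T]) or dist[T] >= -1e-12:
            break
        v = T
        while v != S:
            aid = prev_arc[v]
            if prev_dir[v] == 1:
                arcs[aid][3] = 1
                v = arcs[aid][0]
            else:
                arcs[aid][3] = 0
                v = arcs[aid][1]
        total_cost += dist[T]

    # extract tracks from flow
    succ: dict[int, tuple[int, str | None]] = {}
    starts: list[int] = []
    for aid, (u, v, cost, flow) in enumerate(arcs):
        if flow != 1:
            continue
        if u == S:
            starts.append((v - 2) // 2)
        elif v != T and u >= 2 and v >= 2 and u % 2 == 1:  # out -> in transition
            succ[(u - 3) // 2] = ((v - 2) // 2, modes.get(aid))
    tracks: list[Track] = []
    for tid, i in enumerate(sorted(starts)):
        entries = [(graph.detections[i].frame, graph.detections[i])]
        rapid: list[bool] = []
        cur = i
        while cur in succ:
            nxt, mode = succ[cur]
            entries.append((graph.detections[nxt].frame, graph.detections[nxt]))
            rapid.append(mode == RAPID)
            cur = nxt
        tracks.append(Track(track_id=tid, entries=entries, is_rapid=rapid))
    return TrackSolution(tracks=tracks, total_cost=total_cost)


def track_movie(
    movie: Movie,
    detections: list[list[Detection]],
    motion: MotionParams,
) -> TrackSolution:
    """Convenience wrapper: rapid-motion gating, graph build, exact solve."""
    flags = rapid_motion_flags(
        movie, detections, window_px=motion.rapid_window_px, z_threshold=motion.rapid_z_threshold
    )
    graph = build_track_graph(detections, motion, flags)
    return solve_tracks(graph)
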