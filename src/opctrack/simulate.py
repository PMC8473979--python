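"""Synthetic spinal-cord time-lapse generator with ground truth.

Emulates lateral-view *olig2:egfp*-style movies: a band of
near-stationary cells plus a minority of dorsally / ventrally migrating
cells, rendered as isotropic Gaussian blobs over a uniform background,
with exponential photobleaching, slow global drift and additive
Gaussian noise.  The dorsal axis is decreasing row index (image "up"),
used consistently throughout the package.

Trajectories of different cells keep a minimum same-frame separation,
mimicking the mutual exclusion (contact repulsion) of tiling cells and
keeping individual cells resolvable.

Everything applied to the movie is recorded in :class:`GroundTruth`, so
detection, registration, bleach correction, tracking and classification
can all be scored against known answers.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import SimConfig
from .errors import ConfigurationError, ParseError
from .movie import Movie

LABEL_STATIONARY = "stationary"
LABEL_DORSAL = "dorsal_migratory"
LABEL_VENTRAL = "ventral_migratory"


@dataclass
class GroundTruth:
    """True per-frame cell positions, labels and applied corruptions.

    ``positions[i, t]`` is the as-imaged centroid (y, x) in pixels of
    cell ``i`` at frame ``t`` (drift included); entries are NaN where
    ``present[i, t]`` is False (cell outside the field).
    """

    cell_ids: np.ndarray        # (n_cells,) int
    positions: np.ndarray       # (n_cells, n_frames, 2) float, NaN when absent
    present: np.ndarray         # (n_cells, n_frames) bool
    labels: list[str]           # per cell
    applied_drift: np.ndarray   # (n_frames, 2) cumulative (dy, dx) px
    applied_bleach: np.ndarray  # (n_frames,) multiplicative factor

    @property
    def n_frames(self) -> int:
        return self.applied_drift.shape[0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def equals(self, other: "GroundTruth") -> bool:
        if self.n_cells != other.n_cells or self.n_frames != other.n_frames:
            return False
        if list(self.cell_ids) != list(other.cell_ids) or self.labels != other.labels:
            return False
        if not np.array_equal(self.present, other.present):
            return False
        same_pos = np.array_equal(
            np.nan_to_num(self.positions, nan=-1.0), np.nan_to_num(other.positions, nan=-1.0)
        )
        return (
            same_pos
            and np.array_equal(self.applied_drift, other.applied_drift)
            and np.array_equal(self.applied_bleach, other.applied_bleach)
        )


def _sample_trajectories(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Deterministic (jitter-free) trajectories for all cells, (n_cells, T, 2)."""
    T = config.n_frames
    H, W = config.height_px, config.width_px
    margin = max(6.0, 3.0 * config.cell_sigma_px)
    travel_px = (
        config.migratory_speed_um_per_min * config.frame_interval_min * (T - 1) / config.pixel_size_um
    )
    min_sep = max(8.0, 4.0 * config.cell_sigma_px)

    # migratory cells are placed first: their whole trajectory needs a clear
    # corridor, which is much easier to find in an empty field
    specs: list[tuple[str, float, float]] = []  # (label, row_lo, row_hi) start-row range
    band_lo, band_hi = 0.45 * H, H - margin
    for _ in range(config.n_dorsal_migratory):
        specs.append((LABEL_DORSAL, margin + travel_px, H - margin))
    for _ in range(config.n_ventral_migratory):
        specs.append((LABEL_VENTRAL, margin, H - margin - travel_px))
    for _ in range(config.n_stationary):
        specs.append((LABEL_STATIONARY, max(margin, band_lo), band_hi))

    t = np.arange(T)[:, None]  # (T, 1)
    paths: list[np.ndarray] = []
    labels: list[str] = []
    for label, row_lo, row_hi in specs:
        if row_lo > row_hi or W - margin <= margin:
            raise ConfigurationError(
                "field too small for the requested cells: a trajectory would start or end outside it"
            )
        step = config.migratory_speed_um_per_min * config.frame_interval_min / config.pixel_size_um
        if label == LABEL_DORSAL:
            vel = np.array([-step, 0.0])
        elif label == LABEL_VENTRAL:
            vel = np.array([step, 0.0])
        else:
            vel = np.zeros(2)
        placed = False
        for _attempt in range(2000):
            start = np.array(
                [rng.uniform(row_lo, row_hi), rng.uniform(margin, W - margin)]
            )
            path = start[None, :] + t * vel[None, :]
            ok = True
            for prev in paths:
                if np.min(np.hypot(*(path - prev).T)) < min_sep:
                    ok = False
                    break
            if ok:
                paths.append(path)
                labels.append(label)
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                "could not place all cells with the required separation; "
                "reduce cell counts or enlarge the field"
            )
    if not paths:
        return np.zeros((0, T, 2)), []
    return np.stack(paths), labels


def _render_frame(
    canvas: np.ndarray, centers: np.ndarray, amplitude: float, sigma: float
) -> None:
    """Add isotropic Gaussian blobs (analytic, subpixel-exact) in place."""
    H, W = canvas.shape
    r = int(math.ceil(4.0 * sigma))
    for cy, cx in centers:
        y0, y1 = int(math.floor(cy)) - r, int(math.floor(cy)) + r + 1
        x0, x1 = int(math.floor(cx)) - r, int(math.floor(cx)) + r + 1
        y0c, y1c = max(y0, 0), min(y1, H)
        x0c, x1c = max(x0, 0), min(x1, W)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy = np.arange(y0c, y1c)[:, None] - cy
        xx = np.arange(x0c, x1c)[None, :] - cx
        canvas[y0c:y1c, x0c:x1c] += amplitude * np.exp(
            -(yy**2 + xx**2) / (2.0 * sigma**2)
        )


def simulate_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Generate a seeded synthetic movie and its ground truth.

    Frame ``t`` is ``bleach(t) * (background + blobs)`` plus Gaussian
    noise, with every blob centre shifted by the cumulative drift
    ``t * drift_px_per_frame``.  Identical configs (including seed)
    produce bit-identical movies.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_jitter, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    T, H, W = config.n_frames, config.height_px, config.width_px
    base_paths, labels = _sample_trajectories(config, rng_place)
    n_cells = base_paths.shape[0]

    jitter = (
        rng_jitter.normal(0.0, config.jitter_sd_px, size=(n_cells, T, 2))
        if config.jitter_sd_px > 0 and n_cells
        else np.zeros((n_cells, T, 2))
    )
    drift = np.arange(T)[:, None] * np.asarray(config.drift_px_per_frame)[None, :]
    bleach = np.exp(-config.bleach_rate_per_frame * np.arange(T))

    positions = base_paths + jitter + drift[None, :, :]  # as-imaged coordinates
    present = np.ones((n_cells, T), dtype=bool)
    if n_cells:
        present &= (positions[:, :, 0] >= 0) & (positions[:, :, 0] < H)
        present &= (positions[:, :, 1] >= 0) & (positions[:, :, 1] < W)

    data = np.empty((T, H, W), dtype=float)
    for t in range(T):
        canvas = np.full((H, W), float(config.background_level))
        if n_cells:
            # render every blob whose centre is within reach of the field
            near = (
                (positions[:, t, 0] > -4 * config.cell_sigma_px)
                & (positions[:, t, 0] < H + 4 * config.cell_sigma_px)
                & (positions[:, t, 1] > -4 * config.cell_sigma_px)
                & (positions[:, t, 1] < W + 4 * config.cell_sigma_px)
            )
            _render_frame(canvas, positions[near, t, :], config.cell_amplitude, config.cell_sigma_px)
        data[t] = bleach[t] * canvas
    if config.noise_sd > 0:
        data += rng_noise.normal(0.0, config.noise_sd, size=data.shape)

    pos_out = positions.copy()
    if n_cells:
        pos_out[~present] = np.nan
    gt = GroundTruth(
        cell_ids=np.arange(n_cells),
        positions=pos_out,
        present=present,
        labels=labels,
        applied_drift=drift,
        applied_bleach=bleach,
    )
    movie = Movie(data, config.pixel_size_um, config.frame_interval_min)
    return movie, gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Serialize ground truth as CSV plus a JSON sidecar (drift / bleach)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "frame", "y_px", "x_px", "present", "label"])
        for i, cid in enumerate(gt.cell_ids):
            for t in range(gt.n_frames):
                y, x = gt.positions[i, t]
                writer.writerow(
                    [
                        int(cid),
                        t,
                        "nan" if np.isnan(y) else repr(float(y)),
                        "nan" if np.isnan(x) else repr(float(x)),
                        int(gt.present[i, t]),
                        gt.labels[i],
                    ]
                )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "n_frames": int(gt.n_frames),
                "applied_drift": [[repr(float(v)) for v in row] for row in gt.applied_drift],
                "applied_bleach": [repr(float(v)) for v in gt.applied_bleach],
            }
        )
    )


def read_ground_truth(path) -> GroundTruth:
    """Read ground truth written by :func:`write_ground_truth` (lossless)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    try:
        meta = json.loads(sidecar.read_text())
        n_frames = int(meta["n_frames"])
        drift = np.array([[float(v) for v in row] for row in meta["applied_drift"]], dtype=float)
        drift = drift.reshape(n_frames, 2)
        bleach = np.array([float(v) for v in meta["applied_bleach"]], dtype=float)
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed ground-truth sidecar {sidecar}: {exc}") from exc

    rows: dict[int, dict] = {}
    try:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != ["cell_id", "frame", "y_px", "x_px", "present", "label"]:
                raise ParseError(f"unexpected ground-truth columns in {path}")
            for rec in reader:
                cid = int(rec["cell_id"])
                cell = rows.setdefault(
                    cid,
                    {
                        "pos": np.full((n_frames, 2), np.nan),
                        "present": np.zeros(n_frames, dtype=bool),
                        "label": rec["label"],
                    },
                )
                t = int(rec["frame"])
                cell["pos"][t] = (float(rec["y_px"]), float(rec["x_px"]))
                cell["present"][t] = bool(int(rec["present"]))
    except (ValueError, KeyError) as exc:
        raise ParseError(f"malformed ground-truth file {path}: {exc}") from exc

    cell_ids = np.array(sorted(rows), dtype=int)
    if len(cell_ids):
        positions = np.stack([rows[c]["pos"] for c in cell_ids])
        present = np.stack([rows[c]["present"] for c in cell_ids])
        labels = [rows[c]["label"] for c in cell_ids]
    else:
        positions = np.zeros((0, n_frames, 2))
        present = np.zeros((0, n_frames), dtype=bool)
        labels = []
    return GroundTruth(cell_ids, positions, present, labels, drift, bleach)
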