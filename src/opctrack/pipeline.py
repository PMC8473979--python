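"""End-to-end orchestration: preprocess, detect, track, classify, count.

``run_pipeline`` executes bleach correction, drift registration, blob
detection, temporal-consistency correction, min-cost-flow linking,
motility statistics and migratory classification in order, optionally
writing every intermediate table plus a summary JSON.  All randomness
in a run flows from the single seed in the config, and identical
config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as opio
from .classify import CellLabel, classify_migratory, count_migratory
from .config import PipelineConfig
from .detect import Detection, detect_movie, enforce_temporal_consistency
from .errors import OpctrackError
from .motility import MotilityStats, compute_motility
from .movie import Movie
from .preprocess import correct_photobleach, register_global
from .simulate import simulate_movie
from .track import TrackSolution, track_movie

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    movie: Movie
    registered: Movie
    shifts: np.ndarray
    detections: list[list[Detection]]
    solution: TrackSolution
    motility: list[MotilityStats]
    labels: list[CellLabel]
    summary: dict


def run_pipeline(
    config: PipelineConfig, movie: Movie | None = None, outdir=None
) -> PipelineResult:
    """Run the full analysis on a movie (simulated from config when omitted)."""
    cfg_hash = opio.config_hash(config.to_dict())
    outdir_path = None
    if outdir is not None:
        outdir_path = Path(outdir)
        outdir_path.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []

    def _artifact(name, writer):
        if outdir_path is not None:
            writer(outdir_path / name)
            completed.append(name)

    stage = "simulate"
    try:
        if movie is None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            movie, _gt = simulate_movie(sim_cfg)
        calib = movie  # Movie carries the calibration

        stage = "preprocess"
        logger.info("stage preprocess: bleach correction + registration (%d frames)", movie.n_frames)
        corrected = correct_photobleach(movie)
        reg = register_global(
            corrected,
            reference=config.preprocess.reference_frame,
            upsample_factor=config.preprocess.upsample_factor,
        )
        _artifact(
            "shifts.csv",
            lambda p: opio.write_table(_shifts_frame(reg.shifts), p, cfg_hash),
        )

        stage = "detect"
        detections = detect_movie(reg.registered.data, config.detect)
        n_det = sum(len(d) for d in detections)
        logger.info("stage detect: %d raw detections", n_det)

        stage = "temporal_consistency"
        detections = enforce_temporal_consistency(detections, config.preprocess.max_link_px)
        _artifact(
            "detections.csv",
            lambda p: opio.write_table(opio.detections_to_frame(detections), p, cfg_hash),
        )

        stage = "track"
        solution = track_movie(reg.registered, detections, config.motion)
        logger.info(
            "stage track: %d tracks, solution cost %.3f", len(solution.tracks), solution.total_cost
        )
        _artifact(
            "tracks.csv",
            lambda p: opio.write_table(opio.tracks_to_frame(solution.tracks), p, cfg_hash),
        )

        stage = "motility"
        stats = [
            compute_motility(tr, calib)
            for tr in solution.tracks
            if len(tr.entries) >= 2
        ]

        stage = "classify"
        usable = [tr for tr in solution.tracks if len(tr.entries) >= 2]
        if usable:
            labels, _null = classify_migratory(
                usable,
                calib,
                alpha=config.classify.alpha,
                robust=config.classify.robust_null,
                direction_threshold_um=config.classify.direction_threshold_um,
            )
        else:
            labels = []
        _artifact(
            "labels.csv", lambda p: opio.write_table(opio.labels_to_frame(labels), p, cfg_hash)
        )

        stage = "summary"
        counts = count_migratory(labels)
        summary = {
            "counts": counts,
            "n_tracks": len(solution.tracks),
            "n_detections": n_det,
            "solution_cost": round(float(solution.total_cost), 9),
            "per_track": [
                {
                    "track_id": s.track_id,
                    "distance_um": round(float(s.distance_um), 6),
                    "avg_speed_um_per_min": round(float(s.avg_speed_um_per_min), 6),
                    "net_dv_um": round(float(s.net_dv_um), 6),
                    "duration_min": round(float(s.duration_min), 6),
                }
                for s in stats
            ],
            "seed": config.seed,
        }
        _artifact("summary.json", lambda p: opio.write_json(summary, p, cfg_hash))
    except OpctrackError as exc:
        raise OpctrackError(
            f"pipeline failed at stage '{stage}' "
            f"(completed artifacts: {completed or 'none'}): {exc}"
        ) from exc

    return PipelineResult(
        movie=movie,
        registered=reg.registered,
        shifts=reg.shifts,
        detections=detections,
        solution=solution,
        motility=stats,
        labels=labels,
        summary=summary,
    )


def _shifts_frame(shifts: np.ndarray):
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": np.arange(shifts.shape[0]),
            "dy_px": shifts[:, 0],
            "dx_px": shifts[:, 1],
        }
    )
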