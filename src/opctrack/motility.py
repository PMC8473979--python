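"""Trajectory motility statistics.

All statistics are computed on 2-D projected lateral-view coordinates.
The dorsal axis is decreasing row index, so the signed dorsoventral
displacement is ``-(delta row) * pixel_size_um`` with positive values
meaning dorsal movement.  Distance traveled sums the magnitudes of
displacement between consecutive observed time points (a gap
contributes its straight-line displacement); instantaneous velocity is
the average velocity across one step using the actual elapsed time; the
overall average speed is distance traveled over total elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import Calibration
from .errors import UndefinedStatisticError


class Direction(str, Enum):
    DORSAL = "dorsal"
    VENTRAL = "ventral"
    NONE = "none"


@dataclass
class MotilityStats:
    """Per-track summary of the motility quantities."""

    track_id: int
    distance_um: float
    inst_velocity: np.ndarray        # (m-1, 2) (v_y, v_x) um/min, image axes
    inst_speed: np.ndarray           # (m-1,) um/min
    avg_speed_um_per_min: float
    net_dv_um: float                 # signed, + = dorsal
    duration_min: float


def _positions_um(track, calib: Calibration) -> tuple[np.ndarray, np.ndarray]:
    frames = np.asarray(track.frames, dtype=float)
    pos = np.asarray(track.positions, dtype=float) * calib.pixel_size_um
    if len(frames) < 2:
        raise UndefinedStatisticError(
            f"track {getattr(track, 'track_id', '?')}: need >= 2 entries for motility statistics"
        )
    if np.any(np.diff(frames) <= 0):
        raise UndefinedStatisticError("track frames must be strictly increasing")
    return frames, pos


def distance_traveled(track, calib: Calibration) -> float:
    """Total path length in micrometres over consecutive observed points."""
    _, pos = _positions_um(track, calib)
    return float(np.hypot(*np.diff(pos, axis=0).T).sum())


def instantaneous_velocity(track, calib: Calibration) -> np.ndarray:
    """Per-step average velocity (v_y, v_x) in um/min; gaps use elapsed time."""
    frames, pos = _positions_um(track, calib)
    dt_min = np.diff(frames) * calib.frame_interval_min
    return np.diff(pos, axis=0) / dt_min[:, None]


def instantaneous_speed(track, calib: Calibration) -> np.ndarray:
    v = instantaneous_velocity(track, calib)
    return np.hypot(v[:, 0], v[:, 1])


def average_speed(track, calib: Calibration) -> float:
    """Distance traveled divided by the total elapsed time, um/min."""
    frames, _ = _positions_um(track, calib)
    duration = (frames[-1] - frames[0]) * calib.frame_interval_min
    if duration <= 0:
        raise UndefinedStatisticError("zero duration; average speed undefined")
    return distance_traveled(track, calib) / duration


def net_dorsoventral_um(track, calib: Calibration) -> float:
    """Signed net displacement along the dorsoventral axis (+ = dorsal)."""
    _, pos = _positions_um(track, calib)
    return float(-(pos[-1, 0] - pos[0, 0]))


def migration_direction(
    track, calib: Calibration, threshold_um: float = 2.0
) -> Direction:
    """Dorsal / ventral / none by the sign of the net dorsoventral displacement.

    A magnitude below ``threshold_um`` is reported as ``none``.
    """
    net = net_dorsoventral_um(track, calib)
    if abs(net) < threshold_um:
        return Direction.NONE
    return Direction.DORSAL if net > 0 else Direction.VENTRAL


def compute_motility(track, calib: Calibration) -> MotilityStats:
    """All motility statistics for one track."""
    frames, _ = _positions_um(track, calib)
    v = instantaneous_velocity(track, calib)
    return MotilityStats(
        track_id=int(getattr(track, "track_id", -1)),
        distance_um=distance_traveled(track, calib),
        inst_velocity=v,
        inst_speed=np.hypot(v[:, 0], v[:, 1]),
        avg_speed_um_per_min=average_speed(track, calib),
        net_dv_um=net_dorsoventral_um(track, calib),
        duration_min=float((frames[-1] - frames[0]) * calib.frame_interval_min),
    )
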