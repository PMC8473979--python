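"""Movie and table I/O.

Movies are multi-page TIFF, one page per frame, 16-bit unsigned,
row-major; physical calibration always comes from the config, never
from TIFF tags.  Tables are UTF-8 comma-separated with a header row and
'.' decimals, preceded by one comment line carrying the package version
and the config hash so every artifact is traceable to the run that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ParseError, UnsupportedFormatError
from .movie import Movie


def write_movie(movie: Movie, path) -> None:
    """Write a movie as an unsigned 16-bit multi-page TIFF (clipped, rounded)."""
    data = np.clip(np.rint(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_movie(path, pixel_size_um: float = 0.5, frame_interval_min: float = 1.0) -> Movie:
    """Read a single-channel multi-page TIFF into a :class:`Movie`."""
    try:
        data = tifffile.imread(Path(path))
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected a single-channel T x H x W stack, got shape {data.shape}"
        )
    if data.shape[-1] in (3, 4) and data.ndim == 3 and data.shape[-1] < 5 <= data.shape[0]:
        raise UnsupportedFormatError(f"{path}: RGB(A) input is not supported")
    return Movie(data.astype(float), pixel_size_um, frame_interval_min)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def metadata_line(cfg_hash: str) -> str:
    return f"# opctrack v{__version__} config={cfg_hash}"


def write_table(df: pd.DataFrame, path, cfg_hash: str = "unknown") -> None:
    """Write a CSV with the metadata comment line prepended."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(metadata_line(cfg_hash) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(Path(path), comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc


def write_json(obj: dict, path, cfg_hash: str = "unknown") -> None:
    """Deterministic JSON output (sorted keys) with embedded metadata."""
    payload = {"_meta": {"version": __version__, "config": cfg_hash}}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2, default=_json_default))


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return str(value)


def detections_to_frame(detections) -> pd.DataFrame:
    """Flatten per-frame detections into the detections table."""
    rows = []
    cid = 0
    for frame_dets in detections:
        for d in frame_dets:
            rows.append(
                {
                    "frame": d.frame,
                    "cell_candidate_id": cid,
                    "y_px": d.centroid[0],
                    "x_px": d.centroid[1],
                    "area_px": d.area,
                    "z_score": d.z_score,
                    "q_value": d.q_value,
                }
            )
            cid += 1
    return pd.DataFrame(
        rows,
        columns=["frame", "cell_candidate_id", "y_px", "x_px", "area_px", "z_score", "q_value"],
    )


def tracks_to_frame(tracks) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        prev_frame = None
        for k, (frame, det) in enumerate(tr.entries):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frame,
                    "y_px": det.centroid[0],
                    "x_px": det.centroid[1],
                    "gap_flag": bool(prev_frame is not None and frame - prev_frame > 1),
                    "rapid_flag": bool(k > 0 and tr.is_rapid[k - 1]),
                }
            )
            prev_frame = frame
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "y_px", "x_px", "gap_flag", "rapid_flag"]
    )


def labels_to_frame(labels) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": lab.track_id,
                "is_opc": lab.is_opc,
                "p_value": lab.p_value_trace,
                "direction": lab.direction.value,
            }
            for lab in labels
        ],
        columns=["track_id", "is_opc", "p_value", "direction"],
    )
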