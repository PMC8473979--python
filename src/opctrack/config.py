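"""Configuration dataclasses for every pipeline stage.

All parameters that the underlying methods do not pin down (acquisition
calibration, detection scale, motion-model widths, significance levels)
are exposed here and validated eagerly, so a bad value fails at load
time rather than mid-pipeline.  ``from_dict`` constructors reject
unknown keys to catch typos in JSON configs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigurationError


def _build(cls, data: Mapping):
    """Construct a config dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{cls.__name__}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                value = _NESTED[f.name]._from_dict(value)
            kwargs[f.name] = value
    return cls(**kwargs)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class Calibration:
    """Physical calibration of a movie: spatial and temporal sampling."""

    pixel_size_um: float = 0.5
    frame_interval_min: float = 1.0

    def __post_init__(self):
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_interval_min > 0, "frame_interval_min must be > 0")

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)


@dataclass
class SimConfig:
    """Parameters of the synthetic spinal-cord movie generator.

    The defaults describe a lateral-view field with a dense band of
    near-stationary pMN-domain cells and a minority of directed
    dorsal/ventral migrators, imaged with mild photobleaching and
    additive Gaussian noise.
    """

    n_frames: int = 40
    frame_interval_min: float = 1.0
    height_px: int = 128
    width_px: int = 128
    pixel_size_um: float = 0.5
    n_stationary: int = 15
    n_dorsal_migratory: int = 3
    n_ventral_migratory: int = 2
    cell_sigma_px: float = 2.0
    cell_amplitude: float = 1000.0
    migratory_speed_um_per_min: float = 1.0
    jitter_sd_px: float = 0.15
    bleach_rate_per_frame: float = 0.01
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 50.0
    background_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        self.drift_px_per_frame = tuple(float(v) for v in self.drift_px_per_frame)
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(
            min(self.n_stationary, self.n_dorsal_migratory, self.n_ventral_migratory) >= 0,
            "cell counts must be >= 0",
        )
        _require(self.height_px > 0 and self.width_px > 0, "field dimensions must be positive")
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_interval_min > 0, "frame_interval_min must be > 0")
        _require(self.cell_sigma_px > 0, "cell_sigma_px must be > 0")
        _require(self.bleach_rate_per_frame >= 0, "bleach_rate_per_frame must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.jitter_sd_px >= 0, "jitter_sd_px must be >= 0")
        _require(len(self.drift_px_per_frame) == 2, "drift_px_per_frame must be a 2-vector")

    @property
    def n_cells(self) -> int:
        return self.n_stationary + self.n_dorsal_migratory + self.n_ventral_migratory

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.frame_interval_min)

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        return cls._from_dict(json.loads(Path(path).read_text()))


@dataclass
class DetectParams:
    """Blob-detection parameters.

    ``threshold_sweep`` is a strictly decreasing list of absolute
    response thresholds; ``None`` derives a robust per-frame sweep from
    the response's median and MAD.
    """

    sigma_px: float = 2.0
    threshold_sweep: Sequence[float] | None = None
    min_area_px: int = 5
    max_area_px: int = 400
    alpha_fdr: float = 0.05

    def __post_init__(self):
        _require(self.sigma_px > 0, "sigma_px must be > 0")
        _require(0 < self.min_area_px <= self.max_area_px, "need 0 < min_area_px <= max_area_px")
        _require(0 < self.alpha_fdr < 1, "alpha_fdr must be in (0, 1)")
        if self.threshold_sweep is not None:
            sweep = [float(t) for t in self.threshold_sweep]
            _require(len(sweep) > 0, "threshold_sweep must be non-empty")
            _require(
                all(a > b for a, b in zip(sweep, sweep[1:])),
                "threshold_sweep must be strictly decreasing",
            )
            self.threshold_sweep = sweep

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)


@dataclass
class MotionParams:
    """Mixed motion model for the min-cost-flow linker.

    Two isotropic Gaussian displacement regimes: ``sigma_normal_px`` for
    ordinary frame-to-frame motion and ``sigma_rapid_px`` for gated
    rapid jumps.  Entry/exit cost is ``-log(p_birth)``; each linked
    detection contributes ``log((1 - p_det) / p_det)`` (a reward when
    ``p_det > 0.5``).
    """

    sigma_normal_px: float = 2.0
    sigma_rapid_px: float = 8.0
    max_gap_frames: int = 2
    gap_penalty: float = 1.0
    p_birth: float = 0.01
    p_det: float = 0.98
    cutoff_sigmas: float = 5.0
    rapid_window_px: int = 6
    rapid_z_threshold: float = 3.0

    def __post_init__(self):
        _require(self.sigma_normal_px > 0, "sigma_normal_px must be > 0")
        _require(self.sigma_rapid_px > self.sigma_normal_px, "sigma_rapid_px must exceed sigma_normal_px")
        _require(self.max_gap_frames >= 1, "max_gap_frames must be >= 1")
        _require(self.gap_penalty >= 0, "gap_penalty must be >= 0")
        _require(0 < self.p_birth < 1, "p_birth must be in (0, 1)")
        _require(0 < self.p_det < 1, "p_det must be in (0, 1)")
        _require(self.cutoff_sigmas > 0, "cutoff_sigmas must be > 0")
        _require(self.rapid_window_px >= 1, "rapid_window_px must be >= 1")
        _require(self.rapid_z_threshold > 0, "rapid_z_threshold must be > 0")

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)


@dataclass
class ClassifyParams:
    """Migratory-cell hypothesis test parameters."""

    alpha: float = 0.01
    robust_null: bool = True
    direction_threshold_um: float = 2.0

    def __post_init__(self):
        _require(0 < self.alpha < 1, "alpha must be in (0, 1)")
        _require(self.direction_threshold_um >= 0, "direction_threshold_um must be >= 0")

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)


@dataclass
class PreprocessParams:
    """Bleach-correction / registration options."""

    reference_frame: int = 0
    upsample_factor: int = 50
    max_link_px: float = 6.0  # temporal-consistency matching radius

    def __post_init__(self):
        _require(self.reference_frame >= 0, "reference_frame must be >= 0")
        _require(self.upsample_factor >= 1, "upsample_factor must be >= 1")
        _require(self.max_link_px > 0, "max_link_px must be > 0")

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)


_NESTED: dict[str, type] = {}


@dataclass
class PipelineConfig:
    """Full configuration of the end-to-end pipeline."""

    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detect: DetectParams = field(default_factory=DetectParams)
    motion: MotionParams = field(default_factory=MotionParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    calibration: Calibration = field(default_factory=Calibration)
    seed: int = 0

    @classmethod
    def _from_dict(cls, d):
        return _build(cls, d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls._from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NESTED.update(
    simulate=SimConfig,
    preprocess=PreprocessParams,
    detect=DetectParams,
    motion=MotionParams,
    classify=ClassifyParams,
    calibration=Calibration,
)
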