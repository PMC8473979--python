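"""The in-memory movie container used by every stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass
class Movie:
    """A single-channel time-lapse stack with physical calibration.

    Attributes
    ----------
    data : (T, H, W) float array
        Intensity stack, one 2-D frame per time point.
    pixel_size_um : float
        Lateral sampling, micrometres per pixel.
    frame_interval_min : float
        Time between consecutive frames, minutes.
    """

    data: np.ndarray
    pixel_size_um: float = 0.5
    frame_interval_min: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError(f"movie data must be T x H x W, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ConfigurationError("a movie needs at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ConfigurationError("calibration values must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("movie intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "Movie":
        return Movie(data, self.pixel_size_um, self.frame_interval_min)
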