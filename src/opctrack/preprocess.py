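"""Photobleaching correction and global drift registration.

Bleach correction standardizes every frame to the whole-movie mean and
variance (an affine per-frame map, hence exactly idempotent and
invariant to pure multiplicative bleach).  Drift from larval growth is
removed by pure-translation registration: phase cross-correlation with
subpixel peak refinement against a reference frame, followed by linear
resampling with out-of-field pixels filled by the frame median so edge
effects cannot create phantom detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .errors import ConfigurationError, DegenerateFrameError, RegistrationError
from .movie import Movie


def correct_photobleach(movie: Movie) -> Movie:
    """Match every frame to the movie's global mean and variance.

    Each frame is mapped affinely: centred, rescaled by the ratio of the
    global to the frame standard deviation, and shifted to the global
    mean.  Raises :class:`DegenerateFrameError` for a zero-variance
    frame (the rescaling is undefined there).
    """
    data = movie.data
    target_mean = float(data.mean())
    target_sd = float(data.std())
    out = np.empty_like(data)
    for t in range(movie.n_frames):
        frame = data[t]
        sd = float(frame.std())
        if sd == 0.0:
            raise DegenerateFrameError(t, "zero variance; bleach correction undefined")
        out[t] = (frame - frame.mean()) * (target_sd / sd) + target_mean
    return movie.copy_with(out)


@dataclass
class RegistrationResult:
    """Estimated per-frame translations and the resampled movie."""

    shifts: np.ndarray  # (T, 2) estimated (dy, dx) of each frame relative to the reference
    registered: Movie


def _estimate_shift(ref: np.ndarray, frame: np.ndarray, upsample_factor: int) -> np.ndarray:
    """Translation of ``frame`` onto ``ref``, robust to locally moving cells.

    A first cross-correlation pass can be dragged by the subpixel
    blending of a coherently moving minority of cells whose displacement
    still overlaps the static correlation peak.  Regions whose aligned
    difference exceeds a quarter of the blob amplitude are therefore
    masked (filled with the median) and the shift re-estimated from the
    static content.  The threshold is amplitude-relative so pure
    interpolation residue never triggers masking, and masking is
    skipped when noise would flag a large fraction of the field.
    """
    offset, _, _ = phase_cross_correlation(
        ref, frame, upsample_factor=upsample_factor, normalization=None
    )
    aligned = ndi.shift(frame, offset, order=1, mode="constant", cval=float(np.median(frame)))
    diff = np.abs(aligned - ref)
    med = float(np.median(diff))
    mad_sigma = 1.4826 * float(np.median(np.abs(diff - med)))
    amplitude = float(np.percentile(ref, 99.9) - np.median(ref))
    if amplitude <= 0:
        return np.asarray(offset)
    thr = max(med + 8.0 * mad_sigma, 0.25 * amplitude)
    mask = ndi.binary_dilation(diff > thr, iterations=4)
    frac = mask.mean()
    if frac == 0.0 or frac > 0.3:
        return np.asarray(offset)
    ref_masked = ref.copy()
    ref_masked[mask] = np.median(ref)
    # transfer the mask into the moving frame's coordinates
    mask_frame = ndi.shift(mask.astype(float), -np.asarray(offset), order=0) > 0.5
    frame_masked = frame.copy()
    frame_masked[mask_frame] = np.median(frame)
    if ref_masked.std() == 0.0 or frame_masked.std() == 0.0:
        return np.asarray(offset)
    offset2, _, _ = phase_cross_correlation(
        ref_masked, frame_masked, upsample_factor=upsample_factor, normalization=None
    )
    return np.asarray(offset2)


def register_global(
    movie: Movie, reference: int = 0, upsample_factor: int = 50
) -> RegistrationResult:
    """Remove slow global translation against a reference frame.

    ``shifts[t]`` is the estimated displacement of frame ``t`` relative
    to the reference (so a drift of ``d`` px/frame appears as roughly
    ``d * (t - reference)``); each frame is resampled by the negated
    shift.  Linear interpolation is used to avoid the over/undershoot of
    higher-order splines near sharp blobs.
    """
    if not 0 <= reference < movie.n_frames:
        raise ConfigurationError(f"reference frame {reference} outside movie of {movie.n_frames} frames")
    ref = movie.data[reference]
    if ref.std() == 0.0:
        raise RegistrationError(f"reference frame {reference} is constant; registration undefined")

    T = movie.n_frames
    shifts = np.zeros((T, 2))
    out = np.empty_like(movie.data)
    for t in range(T):
        frame = movie.data[t]
        if frame.std() == 0.0:
            raise RegistrationError(f"frame {t} is constant; registration undefined")
        if t == reference:
            out[t] = frame
            continue
        # _estimate_shift returns the shift that maps `frame` onto `ref`
        offset = _estimate_shift(ref, frame, upsample_factor)
        shifts[t] = -offset  # frame position relative to reference
        out[t] = ndi.shift(
            frame, offset, order=1, mode="constant", cval=float(np.median(frame))
        )
    return RegistrationResult(shifts=shifts, registered=movie.copy_with(out))
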