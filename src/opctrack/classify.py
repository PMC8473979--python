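"""Migratory-cell identification by velocity outlier testing.

Most cells in a spinal-cord field of view are effectively stationary,
so the null distribution of instantaneous velocity is learned by
fitting a multivariate Gaussian to all instantaneous velocities of all
traces in the movie.  A cell is called migratory when its trace at
least once shows a significantly high instantaneous velocity: per-step
squared Mahalanobis distances are referred to a chi-square(2) law and
the minimum step p-value is Sidak-combined over the trace length.

The default fit is robust (iterative chi-square trimming with an exact
truncation-consistency correction).  A plain sample-moment fit is
available, but a minority of fast movers inflates it enough to mask
themselves — with a contaminating fraction ``p`` of coherent movers the
naive squared Mahalanobis distance of a mover saturates near
``(1 - p) / p`` regardless of its speed — so the robust fit, which
operationalizes the majority-stationary assumption, is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import Calibration
from .errors import InsufficientDataError
from .motility import Direction, instantaneous_velocity, migration_direction

logger = logging.getLogger(__name__)


@dataclass
class VelocityNull:
    """Fitted Gaussian null of instantaneous velocity (um/min)."""

    mean: np.ndarray        # (2,)
    covariance: np.ndarray  # (2, 2), symmetric positive-definite
    n_obs: int


@dataclass
class CellLabel:
    """Migratory-cell call for one track."""

    track_id: int
    is_opc: bool
    max_mahalanobis_sq: float
    p_value_trace: float
    direction: Direction = Direction.NONE


def _regularize(cov: np.ndarray) -> np.ndarray:
    eps = 1e-9 * np.trace(cov) / 2.0
    if eps <= 0:
        eps = 1e-12
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        logger.warning("degenerate velocity covariance; regularizing with eps*I (eps=%g)", eps)
        return cov + eps * np.eye(2)


def fit_velocity_null(
    velocities: np.ndarray,
    robust: bool = True,
    trim_quantile: float = 0.975,
    n_iter: int = 10,
) -> VelocityNull:
    """Fit the Gaussian velocity null from pooled step velocities.

    With ``robust=True`` (default) the moments are re-estimated on the
    observations inside the ``trim_quantile`` chi-square(2) Mahalanobis
    contour, iterating to a fixed point; the trimmed covariance is
    divided by the exact Gaussian truncation factor
    ``P(chi2_4 <= k) / P(chi2_2 <= k)`` so the estimate stays consistent
    (and hence the test calibrated) under a stationary-majority null.
    """
    v = np.asarray(velocities, dtype=float).reshape(-1, 2)
    if v.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 velocity observations to fit the null, got {v.shape[0]}"
        )
    mean = v.mean(axis=0)
    cov = np.cov(v, rowvar=False)
    if robust and v.shape[0] >= 20:
        # High-breakdown start: componentwise median and MAD scale, so a
        # coherent minority of fast movers cannot mask itself the way it
        # does in the sample moments.
        mean = np.median(v, axis=0)
        mad_sd = 1.4826 * np.median(np.abs(v - mean), axis=0)
        mad_sd = np.maximum(mad_sd, 1e-12)
        cov = np.diag(mad_sd**2)
        k = stats.chi2.ppf(trim_quantile, df=2)
        correction = stats.chi2.cdf(k, df=4) / stats.chi2.cdf(k, df=2)
        for _ in range(n_iter):
            cov_r = _regularize(cov)
            d2 = _mahalanobis_sq(v, mean, cov_r)
            keep = d2 <= k
            if keep.sum() < 3:
                break
            new_mean = v[keep].mean(axis=0)
            new_cov = np.cov(v[keep], rowvar=False) / correction
            if np.allclose(new_mean, mean, atol=1e-12) and np.allclose(new_cov, cov, atol=1e-12):
                mean, cov = new_mean, new_cov
                break
            mean, cov = new_mean, new_cov
    cov = _regularize(np.atleast_2d(cov))
    return VelocityNull(mean=mean, covariance=cov, n_obs=v.shape[0])


def _mahalanobis_sq(v: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = v - mean
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def trace_p_value(velocities: np.ndarray, null: VelocityNull) -> tuple[float, float]:
    """(Sidak-combined trace p-value, max squared Mahalanobis distance)."""
    v = np.asarray(velocities, dtype=float).reshape(-1, 2)
    if v.shape[0] == 0:
        return 1.0, 0.0
    d2 = _mahalanobis_sq(v, null.mean, null.covariance)
    d2max = float(d2.max())
    p_min = stats.chi2.sf(d2max, df=2)
    m = v.shape[0]
    # p = 1 - (1 - p_min)^m, computed stably
    p = float(-np.expm1(m * np.log1p(-min(p_min, 1.0 - 1e-16))))
    return min(max(p, 0.0), 1.0), d2max


def classify_migratory(
    tracks,
    calib: Calibration,
    null: VelocityNull | None = None,
    alpha: float = 0.01,
    robust: bool = True,
    direction_threshold_um: float = 2.0,
) -> tuple[list[CellLabel], VelocityNull]:
    """Label each track migratory (OPC) or not by the velocity outlier test.

    When ``null`` is None it is fitted from the pooled instantaneous
    velocities of all supplied tracks.  Tracks too short for a velocity
    are labelled non-migratory with p = 1.
    """
    if not 0 < alpha < 1:
        raise InsufficientDataError("alpha must be in (0, 1)")
    per_track_v = []
    for tr in tracks:
        if len(tr.frames) >= 2:
            per_track_v.append(instantaneous_velocity(tr, calib))
        else:
            per_track_v.append(np.zeros((0, 2)))
    if null is None:
        pooled = (
            np.vstack([v for v in per_track_v if len(v)])
            if any(len(v) for v in per_track_v)
            else np.zeros((0, 2))
        )
        null = fit_velocity_null(pooled, robust=robust)
    labels = []
    for tr, v in zip(tracks, per_track_v):
        if len(v) == 0:
            logger.info("track %s too short for velocities; labelled non-migratory", tr.track_id)
            labels.append(
                CellLabel(tr.track_id, False, 0.0, 1.0, Direction.NONE)
            )
            continue
        p, d2max = trace_p_value(v, null)
        is_opc = p < alpha
        direction = (
            migration_direction(tr, calib, direction_threshold_um) if is_opc else Direction.NONE
        )
        labels.append(CellLabel(tr.track_id, is_opc, d2max, p, direction))
    return labels, null


def count_migratory(labels: list[CellLabel]) -> dict[str, int]:
    """Per-movie migratory-cell counts: total and by dorsoventral direction."""
    total = sum(1 for lab in labels if lab.is_opc)
    dorsal = sum(1 for lab in labels if lab.is_opc and lab.direction == Direction.DORSAL)
    ventral = sum(1 for lab in labels if lab.is_opc and lab.direction == Direction.VENTRAL)
    return {"total_migratory": total, "dorsal": dorsal, "ventral": ventral}
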