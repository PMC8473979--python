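"""Velocity-null fitting and migratory-cell hypothesis testing."""

import numpy as np
import pytest

from opctrack.classify import (
    VelocityNull,
    classify_migratory,
    count_migratory,
    fit_velocity_null,
    trace_p_value,
)
from opctrack.config import Calibration
from opctrack.errors import InsufficientDataError
from opctrack.motility import Direction
from test_motility import PathTrack

CAL = Calibration(pixel_size_um=1.0, frame_interval_min=1.0)


class TestFit:
    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, (10_000, 2))
        null = fit_velocity_null(v)
        assert np.all(np.abs(null.mean) < 0.05)
        assert np.all(np.abs(null.covariance - np.eye(2)) < 0.05)

    def test_degenerate_input_regularized_with_warning(self, caplog):
        v = np.tile([1.0, 2.0], (50, 1))
        with caplog.at_level("WARNING"):
            null = fit_velocity_null(v, robust=False)
        assert "regularizing" in caplog.text
        np.linalg.cholesky(null.covariance)  # positive-definite now

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_velocity_null(np.zeros((2, 2)))

    def test_jitter_scene_covariance_matches_propagated_analytic_value(self):
        """Positional jitter of SD s gives velocity covariance 2 s^2 / dt^2 I."""
        rng = np.random.default_rng(1)
        jitter_sd, dt = 0.2, 1.5
        pos = rng.normal(0, jitter_sd, (4000, 60, 2))
        v = np.diff(pos, axis=1) / dt
        null = fit_velocity_null(v.reshape(-1, 2))
        expected = 2 * jitter_sd**2 / dt**2
        assert np.allclose(np.diag(null.covariance), expected, rtol=0.05)
        assert abs(null.covariance[0, 1]) < 0.05 * expected

    def test_robust_fit_ignores_minority_of_movers(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 0.1, (4000, 2))
        v[:1000, 0] += 1.0  # 25% coherent movers
        null = fit_velocity_null(v)
        assert np.all(np.abs(np.diag(null.covariance) - 0.01) < 0.005)
        assert np.all(np.abs(null.mean) < 0.05)


class TestClassification:
    def test_extreme_single_step_is_migratory(self):
        null = VelocityNull(np.zeros(2), np.eye(2), 1000)
        v = np.array([[50**0.5, 0.0]])  # Mahalanobis d^2 = 50 on 2 df
        p, d2 = trace_p_value(v, null)
        assert d2 == pytest.approx(50.0)
        assert p < 1e-9

    def test_type_one_error_calibrated(self):
        """Stationary traces with null-consistent jitter: FP rate ~ alpha."""
        rng = np.random.default_rng(5)
        n_traces, m = 2000, 39
        pos = rng.normal(0, 0.1, (n_traces, m + 1, 2))
        v = np.diff(pos, axis=1)
        null = fit_velocity_null(v.reshape(-1, 2))
        alpha = 0.01
        fp = sum(trace_p_value(v[i], null)[0] < alpha for i in range(n_traces))
        se = np.sqrt(alpha * (1 - alpha) / n_traces)
        assert abs(fp / n_traces - alpha) <= 2 * se

    def test_calibration_survives_contamination(self):
        """<= 25% migratory cells in the fit set keep type-I error controlled."""
        rng = np.random.default_rng(6)
        n_traces, m = 2000, 39
        pos = rng.normal(0, 0.1, (n_traces, m + 1, 2))
        v = np.diff(pos, axis=1)
        v[:500, :, 0] -= 1.0  # movers included in the fit, as in practice
        null = fit_velocity_null(v.reshape(-1, 2))
        alpha = 0.01
        fp = sum(trace_p_value(v[i], null)[0] < alpha for i in range(500, n_traces))
        se = np.sqrt(alpha * (1 - alpha) / 1500)
        assert fp / 1500 <= alpha + 2 * se
        detected = sum(trace_p_value(v[i], null)[0] < alpha for i in range(500))
        assert detected >= 475

    def test_speed_scaling_monotonicity(self):
        """Scaling all velocities up never unmarks a migratory cell."""
        rng = np.random.default_rng(7)
        null = VelocityNull(np.zeros(2), 0.01 * np.eye(2), 10_000)
        v = rng.normal(0, 0.1, (30, 2))
        v[3] = (0.6, 0.1)
        p1, _ = trace_p_value(v, null)
        p2, _ = trace_p_value(2.0 * v, null)
        assert p2 <= p1

    def test_short_track_labelled_non_migratory(self):
        tracks = [
            PathTrack([0], [(0, 0)], track_id=0),
            PathTrack(np.arange(30), np.cumsum(np.ones((30, 2)) * 0.01, axis=0), track_id=1),
            PathTrack(np.arange(30), np.random.default_rng(0).normal(0, 0.1, (30, 2)), track_id=2),
        ]
        null = VelocityNull(np.zeros(2), 0.01 * np.eye(2), 1000)
        labels, _ = classify_migratory(tracks, CAL, null=null, alpha=0.01)
        assert labels[0].is_opc is False and labels[0].p_value_trace == 1.0


def test_count_migratory_composition():
    class Lab:
        def __init__(self, is_opc, direction):
            self.track_id = 0
            self.is_opc = is_opc
            self.direction = direction

    labels = [Lab(True, Direction.DORSAL)] * 3 + [Lab(True, Direction.VENTRAL)] * 2 + [
        Lab(False, Direction.NONE)
    ] * 4
    counts = count_migratory(labels)
    assert counts == {"total_migratory": 5, "dorsal": 3, "ventral": 2}


def test_count_migratory_empty():
    assert count_migratory([]) == {"total_migratory": 0, "dorsal": 0, "ventral": 0}
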