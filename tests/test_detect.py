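"""Blob detection, significance control, temporal-consistency correction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import make_blob_frame
from opctrack.config import DetectParams
from opctrack.detect import (
    Detection,
    detect_cells,
    detect_movie,
    enforce_temporal_consistency,
    second_derivative_transform,
)
from opctrack.errors import ConfigurationError


class TestTransform:
    def test_constant_frame_gives_zero_response(self):
        resp = second_derivative_transform(np.full((32, 32), 7.0), 2.0)
        assert np.allclose(resp, 0.0, atol=1e-9)

    def test_peak_at_blob_center_at_matched_scale(self):
        frame = make_blob_frame([(40.0, 60.0)], sigma=3.0)
        resp = second_derivative_transform(frame, 3.0)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(peak[0] - 40) <= 1 and abs(peak[1] - 60) <= 1

    def test_two_separated_blobs_give_two_maxima(self):
        frame = make_blob_frame([(30.0, 30.0), (70.0, 72.0)])
        resp = second_derivative_transform(frame, 2.0)
        maxima = (resp == ndi.maximum_filter(resp, size=9)) & (resp > 0.5 * resp.max())
        coords = np.argwhere(maxima)
        assert len(coords) == 2
        dists = np.sort([np.hypot(*(c - (30, 30))) for c in coords])
        assert dists[0] <= 1.5

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            second_derivative_transform(np.zeros((8, 8)), 0.0)


class TestDetectCells:
    def test_zero_frame_yields_no_detections(self):
        assert detect_cells(np.zeros((64, 64)), DetectParams()) == []

    def test_five_clean_blobs_found_exactly(self):
        rng = np.random.default_rng(0)
        truth = np.array(
            [[20, 20], [20, 70], [50, 45], [80, 20], [80, 75]], float
        ) + rng.uniform(-0.4, 0.4, (5, 2))
        frame = make_blob_frame(truth)
        dets = detect_cells(frame, DetectParams())
        assert len(dets) == 5
        errs = [min(np.hypot(*(truth - d.centroid).T)) for d in dets]
        assert max(errs) <= 0.5

    def test_detections_disjoint_and_q_monotone_in_z(self):
        truth = [(25, 25), (25, 75), (75, 25), (75, 75), (50, 50)]
        frame = make_blob_frame(truth, noise_sd=50.0, seed=5)
        dets = detect_cells(frame, DetectParams())
        assert dets
        seen = set()
        for d in dets:
            keys = {tuple(p) for p in d.pixels}
            assert not keys & seen
            seen |= keys
        by_z = sorted(dets, key=lambda d: d.z_score)
        qs = [d.q_value for d in by_z]
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_noise_stack_false_positive_rate_bounded(self):
        """FDR control: detections on pure noise <= alpha * candidate count."""
        from opctrack.detect import _frame_candidates

        params = DetectParams()
        stack = 100 + np.random.default_rng(7).normal(0, 50, (40, 100, 100))
        dets = detect_movie(stack, params)
        n_fp = sum(len(d) for d in dets)
        n_cand = sum(len(_frame_candidates(stack[t], params)[0]) for t in range(40))
        assert n_fp <= max(1.0, params.alpha_fdr * n_cand)

    def test_empty_sweep_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectParams(threshold_sweep=[])


def _block_detection(frame, y0, y1, x0, x1):
    pix = np.array([(y, x) for y in range(y0, y1) for x in range(x0, x1)], dtype=int)
    return Detection(frame=frame, centroid=pix.mean(axis=0), pixels=pix)


class TestTemporalConsistency:
    def test_consistent_detections_untouched(self):
        frames = [[_block_detection(t, 10, 15, 10, 15)] for t in range(4)]
        out = enforce_temporal_consistency(frames, max_link_px=6.0)
        for orig, new in zip(frames, out):
            assert len(new) == len(orig)
            assert np.array_equal(sorted(map(tuple, new[0].pixels)), sorted(map(tuple, orig[0].pixels)))

    def test_transient_oversegmentation_merged(self):
        whole = lambda t: _block_detection(t, 10, 16, 10, 18)
        frames = [
            [whole(0)],
            [_block_detection(1, 10, 16, 10, 14), _block_detection(1, 10, 16, 14, 18)],
            [whole(2)],
        ]
        out = enforce_temporal_consistency(frames, max_link_px=6.0)
        assert len(out[1]) == 1
        assert len(out[1][0].pixels) == 6 * 8  # pixel mass conserved

    def test_transient_undersegmentation_split(self):
        left = lambda t: _block_detection(t, 10, 16, 10, 14)
        right = lambda t: _block_detection(t, 10, 16, 16, 20)
        fused = _block_detection(1, 10, 16, 10, 20)
        frames = [[left(0), right(0)], [fused], [left(2), right(2)]]
        out = enforce_temporal_consistency(frames, max_link_px=6.0)
        assert len(out[1]) == 2
        assert sum(len(d.pixels) for d in out[1]) == len(fused.pixels)
        centroids = sorted(d.centroid[1] for d in out[1])
        assert centroids[0] < 15 < centroids[1]

    def test_invalid_link_radius(self):
        with pytest.raises(ConfigurationError):
            enforce_temporal_consistency([[], [], []], max_link_px=0.0)
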