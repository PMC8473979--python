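"""Intra-frame cell detection with significance scoring.

Cells are found on the negated scale-normalized Laplacian-of-Gaussian
(second-order derivative) transform of each frame: bright blobs become
positive peaks.  Candidate regions come from a decreasing threshold
sweep on the response (component-tree style); each candidate is emitted
at the threshold maximizing its significance, scored as a two-sample
contrast z between the region's raw intensity and a 2-px-dilated
boundary ring.

Because candidates are, by construction, local maxima of a smoothed
response, their contrast z is biased upward even on pure noise.  The
null for significance is therefore calibrated per frame from *decoys*:
regions extracted by the identical procedure from the negated response
(dark blobs), whose mirrored z distribution estimates the
selection-biased null.  One-sided p-values against that empirical null
are corrected by Benjamini-Hochberg; regions surviving at the requested
FDR and the area bounds are kept, disjointly.

Over-/under-segmentation is then corrected frame by frame by imposing
temporal consistency: merges and splits supported by single/double
matches in both neighbouring frames are accepted whenever they reduce a
total (1 - IoU) cost against those neighbours.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max

from .config import DetectParams
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

_AUTO_SWEEP_MADS = (10.0, 8.0, 6.0, 5.0, 4.0, 3.0)


@dataclass
class Detection:
    """One segmented cell candidate in one frame."""

    frame: int
    centroid: np.ndarray      # (y, x), continuous, 0-based
    pixels: np.ndarray        # (N, 2) integer (y, x) coordinates, 4-connected
    peak_response: float = 0.0
    z_score: float = 0.0
    q_value: float = 1.0

    @property
    def area(self) -> int:
        return len(self.pixels)


def second_derivative_transform(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Negated scale-normalized Laplacian of Gaussian of a frame.

    Bright blobs of scale ``sigma_px`` map to positive peaks; the
    response to a constant frame is identically zero.
    """
    if sigma_px <= 0:
        raise ConfigurationError("sigma_px must be > 0")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ConfigurationError(f"expected a 2-D frame, got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ConfigurationError("frame intensities must be finite")
    # centring removes the DC leak of the truncated discrete LoG kernel,
    # making the response to a constant frame exactly zero
    return -(sigma_px**2) * ndi.gaussian_laplace(frame - frame.mean(), sigma_px)


def _auto_sweep(resp: np.ndarray) -> list[float]:
    """Robust decreasing threshold sweep: median + k * MAD-sigma of the response."""
    med = float(np.median(resp))
    mad = float(np.median(np.abs(resp - med)))
    scale = 1.4826 * mad
    if scale == 0.0:
        # noise-free frame: flat background gives zero MAD, fall back to the
        # standard deviation (driven by whatever structure is present)
        scale = float(resp.std())
    if scale == 0.0:
        return []
    return [med + k * scale for k in _AUTO_SWEEP_MADS]


def _contrast_z(interior: np.ndarray, ring: np.ndarray) -> float:
    """Two-sample z of region interior vs boundary-ring raw intensity."""
    n1, n2 = interior.size, ring.size
    m1, m2 = float(interior.mean()), float(ring.mean())
    if n1 + n2 <= 2:
        return 0.0
    ss = float(((interior - m1) ** 2).sum() + ((ring - m2) ** 2).sum())
    s2 = ss / (n1 + n2 - 2)
    if s2 == 0.0:
        return np.inf if m1 > m2 else 0.0
    return (m1 - m2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))


def _extract_candidates(
    resp: np.ndarray,
    raw: np.ndarray,
    sweep: list[float],
    min_area: int,
    max_area: int,
) -> list[dict]:
    """Threshold-sweep region candidates, each at its max-significance threshold."""
    H, W = resp.shape
    seeds = peak_local_max(
        resp, min_distance=2, threshold_abs=sweep[-1], exclude_border=False
    )
    if len(seeds) == 0:
        return []
    best: dict[int, dict] = {}
    for ti, thr in enumerate(sweep):
        mask = resp >= thr
        lbl, n = ndi.label(mask)  # 4-connectivity
        if n == 0:
            continue
        seed_lab = lbl[seeds[:, 0], seeds[:, 1]]
        hit: dict[int, list[int]] = {}
        for si, lab in enumerate(seed_lab):
            if lab > 0:
                hit.setdefault(int(lab), []).append(si)
        if not hit:
            continue
        objects = ndi.find_objects(lbl)
        for lab, sis in hit.items():
            sl = objects[lab - 1]
            y0 = max(sl[0].start - 3, 0)
            y1 = min(sl[0].stop + 3, H)
            x0 = max(sl[1].start - 3, 0)
            x1 = min(sl[1].stop + 3, W)
            comp = lbl[y0:y1, x0:x1] == lab
            area = int(comp.sum())
            if not (min_area <= area <= max_area):
                continue
            ring = ndi.binary_dilation(comp, iterations=2) & ~mask[y0:y1, x0:x1]
            ring_vals = raw[y0:y1, x0:x1][ring]
            if ring_vals.size < 3:
                continue
            interior_vals = raw[y0:y1, x0:x1][comp]
            z = _contrast_z(interior_vals, ring_vals)
            pixels = np.argwhere(comp) + (y0, x0)
            peak = float(max(resp[seeds[si, 0], seeds[si, 1]] for si in sis))
            cand = {
                "pixels": pixels,
                "z": z,
                "peak": peak,
                "key": (ti, lab),
                "area": area,
            }
            for si in sis:
                cur = best.get(si)
                if cur is None or z > cur["z"]:
                    best[si] = cand
    # deduplicate seeds that settled on the same region
    unique: dict[tuple, dict] = {}
    for cand in best.values():
        unique.setdefault(cand["key"], cand)
    return list(unique.values())


def _weighted_centroid(pixels: np.ndarray, raw: np.ndarray, baseline: float) -> np.ndarray:
    """Background-subtracted intensity-weighted centre of a pixel set."""
    w = raw[pixels[:, 0], pixels[:, 1]] - baseline
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        w = np.ones(len(pixels))
    return (pixels * w[:, None]).sum(axis=0) / w.sum()


def _refine_centroid(
    raw: np.ndarray,
    start: np.ndarray,
    sigma: float,
    baseline: float,
    n_iter: int = 3,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-windowed centre-of-mass refinement.

    The pixel membership of a thresholded region flickers with noise,
    which puts heavy tails on the plain region centroid.  Re-weighting
    the background-subtracted intensity with a Gaussian window centred
    on the running estimate is continuous in the image values and gives
    near-Gaussian localization errors, which the downstream velocity
    outlier test relies on.  Pixels in ``exclude`` (typically owned by
    neighbouring detections) get zero weight so a bright cell passing
    nearby does not drag the estimate.
    """
    H, W = raw.shape
    r = max(2, int(math.ceil(3.0 * sigma)))
    c = np.asarray(start, dtype=float).copy()
    for _ in range(n_iter):
        y0, y1 = max(int(c[0]) - r, 0), min(int(c[0]) + r + 1, H)
        x0, x1 = max(int(c[1]) - r, 0), min(int(c[1]) + r + 1, W)
        if y0 >= y1 or x0 >= x1:
            return c
        yy = np.arange(y0, y1)[:, None]
        xx = np.arange(x0, x1)[None, :]
        g = np.exp(-((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / (2.0 * sigma**2))
        w = np.clip(raw[y0:y1, x0:x1] - baseline, 0.0, None) * g
        if exclude is not None:
            w = w * ~exclude[y0:y1, x0:x1]
        total = w.sum()
        if total <= 0:
            return c
        c = np.array([(w * yy).sum() / total, (w * xx).sum() / total])
    return c


def _frame_candidates(
    frame: np.ndarray, params: DetectParams
) -> tuple[list[dict], list[dict]]:
    """Extract threshold-sweep candidates and dark-blob decoys for one frame."""
    resp = second_derivative_transform(frame, params.sigma_px)
    raw = np.asarray(frame, dtype=float)
    if params.threshold_sweep is not None:
        sweep = list(params.threshold_sweep)
        decoy_sweep = sweep
    else:
        sweep = _auto_sweep(resp)
        decoy_sweep = _auto_sweep(-resp)
    if not sweep:  # constant response (e.g. constant frame): nothing to detect
        return [], []
    cands = _extract_candidates(resp, raw, sweep, params.min_area_px, params.max_area_px)
    decoys = (
        _extract_candidates(-resp, raw, decoy_sweep, params.min_area_px, params.max_area_px)
        if decoy_sweep
        else []
    )
    return cands, decoys


def _decoy_null(decoys: list[dict]) -> tuple[float, float]:
    """Robust location/scale of the mirrored decoy z distribution.

    Decoys undergo the same maximum-seeking selection as candidates, so
    their mirrored z's estimate the selection-biased null.  With too few
    decoys the standard normal null is used.  The scale is clipped to
    [1, 2]: a pooled two-sample z cannot beat unit variance under any
    homogeneous null, while a much larger spread means the decoys are
    heterogeneous artifacts (e.g. resampling sidelobes in noise-free
    frames) rather than a null sample, in which case only their
    location is trusted.
    """
    dz = np.array([-d["z"] for d in decoys], dtype=float)
    dz = dz[np.isfinite(dz)]
    if dz.size >= 5:
        null_mean = float(np.median(dz))
        null_sd = float(np.clip(1.4826 * np.median(np.abs(dz - null_mean)), 1.0, 2.0))
        return null_mean, null_sd
    return 0.0, 1.0


def _candidate_pvalues(cands: list[dict], null_stats: tuple[float, float]) -> np.ndarray:
    """One-sided p-values of candidate contrast z against the decoy null."""
    null_mean, null_sd = null_stats
    zs = np.array([c["z"] for c in cands], dtype=float)
    return stats.norm.sf((zs - null_mean) / null_sd)


def _finalize_frame(
    frame: np.ndarray,
    cands: list[dict],
    qvals: np.ndarray,
    params: DetectParams,
    frame_index: int,
) -> list[Detection]:
    """Keep disjoint FDR-surviving regions and refine their centroids."""
    if not cands:
        return []
    raw = np.asarray(frame, dtype=float)
    zs = np.array([c["z"] for c in cands], dtype=float)

    # survivors, greedily kept disjoint in decreasing significance
    order = sorted(
        range(len(cands)),
        key=lambda i: (-zs[i], -cands[i]["area"], cands[i]["key"]),
    )
    occupied = np.zeros(frame.shape, dtype=bool)
    accepted: list[int] = []
    for i in order:
        if qvals[i] > params.alpha_fdr:
            continue
        pix = cands[i]["pixels"]
        if occupied[pix[:, 0], pix[:, 1]].any():
            continue
        occupied[pix[:, 0], pix[:, 1]] = True
        accepted.append(i)

    baseline = float(np.median(raw))
    out: list[Detection] = []
    for i in accepted:
        pix = cands[i]["pixels"]
        # neighbours' pixels are masked out of the refinement window
        others = occupied.copy()
        others[pix[:, 0], pix[:, 1]] = False
        coarse = _weighted_centroid(pix, raw, baseline)
        out.append(
            Detection(
                frame=frame_index,
                centroid=_refine_centroid(
                    raw, coarse, params.sigma_px, baseline, exclude=others
                ),
                pixels=pix,
                peak_response=cands[i]["peak"],
                z_score=float(zs[i]),
                q_value=float(qvals[i]),
            )
        )
    return out


def detect_cells(
    frame: np.ndarray, params: DetectParams, frame_index: int = 0
) -> list[Detection]:
    """Detect and segment all cells in one (preprocessed) frame.

    Returns pixel-disjoint detections surviving Benjamini-Hochberg FDR
    control at ``params.alpha_fdr`` against the decoy-calibrated null.
    The null uses only this frame's decoys; :func:`detect_movie` pools
    decoys across frames for a steadier calibration.
    """
    if params.threshold_sweep is not None and len(params.threshold_sweep) == 0:
        raise ConfigurationError("threshold_sweep must be non-empty")
    cands, decoys = _frame_candidates(frame, params)
    pvals = _candidate_pvalues(cands, _decoy_null(decoys))
    qvals = stats.false_discovery_control(pvals) if len(cands) else np.zeros(0)
    return _finalize_frame(frame, cands, qvals, params, frame_index)


def detect_movie(movie_data: np.ndarray, params: DetectParams) -> list[list[Detection]]:
    """Detect cells in every frame of a stack.

    The significance null is calibrated from dark-blob decoys pooled
    over all frames, and Benjamini-Hochberg is applied to the pooled
    candidate list, controlling the false-discovery rate per movie
    (sparse noise candidates then need far stronger evidence than under
    frame-by-frame correction, while true cells, which dominate the
    pooled list, are unaffected).
    """
    per_frame = [_frame_candidates(movie_data[t], params) for t in range(movie_data.shape[0])]
    all_decoys = [d for _, decoys in per_frame for d in decoys]
    null_stats = _decoy_null(all_decoys)
    pvals = [_candidate_pvalues(cands, null_stats) for cands, _ in per_frame]
    pooled = np.concatenate([p for p in pvals if len(p)]) if any(len(p) for p in pvals) else None
    if pooled is not None:
        pooled_q = stats.false_discovery_control(pooled)
    out: list[list[Detection]] = []
    k = 0
    for t, (cands, _) in enumerate(per_frame):
        qvals = pooled_q[k : k + len(cands)] if cands else np.zeros(0)
        k += len(cands)
        out.append(_finalize_frame(movie_data[t], cands, qvals, params, t))
    return out


# ---------------------------------------------------------------------------
# temporal consistency


def _pixel_keys(pixels: np.ndarray, width: int) -> np.ndarray:
    return pixels[:, 0].astype(np.int64) * width + pixels[:, 1]


def _iou(a: Detection, b: Detection, width: int) -> float:
    ka, kb = _pixel_keys(a.pixels, width), _pixel_keys(b.pixels, width)
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    if inter == 0:
        return 0.0
    return inter / (ka.size + kb.size - inter)


def _best_iou(det: Detection, neighbors: list[Detection], width: int, max_link_px: float) -> float:
    best = 0.0
    for nb in neighbors:
        if np.hypot(*(det.centroid - nb.centroid)) <= max_link_px + 1e-9:
            best = max(best, _iou(det, nb, width))
    return best


def _merge(a: Detection, b: Detection) -> Detection:
    pixels = np.vstack([a.pixels, b.pixels])
    wa, wb = len(a.pixels), len(b.pixels)
    centroid = (a.centroid * wa + b.centroid * wb) / (wa + wb)
    return Detection(
        frame=a.frame,
        centroid=centroid,
        pixels=pixels,
        peak_response=max(a.peak_response, b.peak_response),
        z_score=max(a.z_score, b.z_score),
        q_value=min(a.q_value, b.q_value),
    )


def _split(det: Detection, ref1: np.ndarray, ref2: np.ndarray) -> tuple[Detection, Detection] | None:
    d1 = np.hypot(*(det.pixels - ref1).T)
    d2 = np.hypot(*(det.pixels - ref2).T)
    take1 = d1 <= d2
    if take1.all() or (~take1).all():
        return None
    parts = []
    for mask in (take1, ~take1):
        pix = det.pixels[mask]
        parts.append(
            Detection(
                frame=det.frame,
                centroid=pix.mean(axis=0),
                pixels=pix,
                peak_response=det.peak_response,
                z_score=det.z_score,
                q_value=det.q_value,
            )
        )
    return parts[0], parts[1]


def enforce_temporal_consistency(
    detections: list[list[Detection]], max_link_px: float
) -> list[list[Detection]]:
    """Correct over-/under-segmentation using both temporal neighbours.

    For every interior frame, candidate merges (two regions whose union
    is matched by a single region in both neighbour frames) and splits
    (one region matched by two in both neighbours) are evaluated; within
    each connected component of conflicting proposals the subset of
    operations minimizing the total ``sum(1 - IoU)`` cost against the
    original neighbour-frame segmentations is applied exhaustively.
    Pixel mass is conserved: merges take unions, splits partition by
    nearest reference centroid.
    """
    if max_link_px <= 0:
        raise ConfigurationError("max_link_px must be > 0")
    if len(detections) < 3:
        return [list(frame) for frame in detections]

    width = 1 + max(
        (int(d.pixels[:, 1].max()) for frame in detections for d in frame),
        default=1,
    )
    out = [list(frame) for frame in detections]
    for t in range(1, len(detections) - 1):
        prev, cur, nxt = detections[t - 1], detections[t], detections[t + 1]
        if not cur:
            continue
        ops: list[dict] = []
        # merge proposals
        for i, j in itertools.combinations(range(len(cur)), 2):
            if np.hypot(*(cur[i].centroid - cur[j].centroid)) > 2 * max_link_px:
                continue
            merged = _merge(cur[i], cur[j])
            ok_prev = any(
                _iou(merged, p, width) > 0 and _iou(cur[i], p, width) > 0 and _iou(cur[j], p, width) > 0
                for p in prev
            )
            ok_nxt = any(
                _iou(merged, p, width) > 0 and _iou(cur[i], p, width) > 0 and _iou(cur[j], p, width) > 0
                for p in nxt
            )
            if ok_prev and ok_nxt:
                ops.append({"kind": "merge", "dets": (i, j), "result": (merged,)})
        # split proposals
        for i, det in enumerate(cur):
            prev_hits = [p for p in prev if _iou(det, p, width) > 0]
            nxt_hits = [p for p in nxt if _iou(det, p, width) > 0]
            if len(prev_hits) < 2 or len(nxt_hits) < 2:
                continue
            prev_hits.sort(key=lambda p: -_iou(det, p, width))
            nxt_hits.sort(key=lambda p: -_iou(det, p, width))
            p1, p2 = prev_hits[0], prev_hits[1]
            # pair neighbour detections across frames by proximity
            if np.hypot(*(p1.centroid - nxt_hits[0].centroid)) <= np.hypot(
                *(p1.centroid - nxt_hits[1].centroid)
            ):
                n1, n2 = nxt_hits[0], nxt_hits[1]
            else:
                n1, n2 = nxt_hits[1], nxt_hits[0]
            ref1 = (p1.centroid + n1.centroid) / 2
            ref2 = (p2.centroid + n2.centroid) / 2
            parts = _split(det, ref1, ref2)
            if parts is not None:
                ops.append({"kind": "split", "dets": (i,), "result": parts})
        if not ops:
            continue

        def config_cost(active: set[int], involved: set[int]) -> float:
            used = set()
            result: list[Detection] = []
            for oi in active:
                used.update(ops[oi]["dets"])
                result.extend(ops[oi]["result"])
            for i in involved - used:
                result.append(cur[i])
            return sum(
                (1.0 - _best_iou(d, prev, width, max_link_px))
                + (1.0 - _best_iou(d, nxt, width, max_link_px))
                for d in result
            )

        # connected components over detections sharing proposals
        parent = list(range(len(cur)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for op in ops:
            d0 = op["dets"][0]
            for d in op["dets"][1:]:
                parent[find(d)] = find(d0)
        comps: dict[int, list[int]] = {}
        for oi, op in enumerate(ops):
            comps.setdefault(find(op["dets"][0]), []).append(oi)

        chosen: list[int] = []
        for root, op_idx in comps.items():
            involved = set()
            for oi in op_idx:
                involved.update(ops[oi]["dets"])
            best_cost = config_cost(set(), involved)
            best_set: set[int] = set()
            pool = op_idx[:12]  # exhaustive over the component's proposals
            for r in range(1, len(pool) + 1):
                for combo in itertools.combinations(pool, r):
                    used: set[int] = set()
                    ok = True
                    for oi in combo:
                        if used & set(ops[oi]["dets"]):
                            ok = False
                            break
                        used.update(ops[oi]["dets"])
                    if not ok:
                        continue
                    cost = config_cost(set(combo), involved)
                    if cost < best_cost - 1e-12:
                        best_cost = cost
                        best_set = set(combo)
            chosen.extend(best_set)

        if chosen:
            drop = set()
            new_dets: list[Detection] = []
            for oi in chosen:
                drop.update(ops[oi]["dets"])
                new_dets.extend(ops[oi]["result"])
            out[t] = [d for i, d in enumerate(cur) if i not in drop] + new_dets
            logger.info(
                "frame %d: applied %d temporal-consistency operation(s)", t, len(chosen)
            )
    return out
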