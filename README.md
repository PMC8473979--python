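# opctrack

Automated detection, tracking and motility classification of
oligodendrocyte progenitor cells (OPCs) in single-channel time-lapse
fluorescence movies of the zebrafish spinal cord, plus the spatial
quantification conventions used for scoring OPC position along the
dorsoventral axis.

During development, OPCs are born in the ventral pMN domain and migrate
— mostly dorsally — to tile the spinal cord. In lateral-view
*olig2:egfp*-style movies most labelled cells barely move, while a
minority migrate directionally; quantifying that minority requires
detecting every cell in every frame, linking detections into
trajectories, and deciding statistically which trajectories are
migratory. `opctrack` implements that entire chain, together with a
synthetic-movie generator with full ground truth, so every stage is
verifiable without any imaging download.

## The pipeline

1. **Photobleaching correction** — every frame is standardized to the
   movie's global mean and variance (an affine map per frame, exactly
   idempotent).
2. **Drift registration** — slow translation from larval growth is
   estimated by subpixel phase cross-correlation against a reference
   frame, with a second masked pass that ignores regions dominated by
   moving cells; frames are resampled by the negated shift.
3. **Detection** — cells are segmented on the negated scale-normalized
   Laplacian-of-Gaussian response by a decreasing threshold sweep; each
   candidate region is scored by a contrast z statistic (interior vs a
   2-px boundary ring of the raw intensity) and kept under
   Benjamini–Hochberg FDR control against an empirical null calibrated
   from dark-blob decoys. Over-/under-segmentation is corrected by
   temporal consistency (merges/splits that minimize a 1 − IoU cost
   against both neighbouring frames).
4. **Tracking** — detections are linked by exact min-cost network flow
   (successive shortest paths) under a mixed motion model: cost of a
   link is the negative log of an isotropic Gaussian displacement
   density with SD σ_normal (or σ_rapid for jumps gated by a regional
   intensity-change test), plus birth/death costs −log p_birth and a
   per-detection confidence reward.
5. **Motility statistics** — per track: distance traveled
   Σ‖p_{k+1} − p_k‖, instantaneous velocity (p_{k+1} − p_k)/Δt and its
   magnitude (speed), overall average speed = distance / duration, and
   signed net dorsoventral displacement (+ = dorsal).
6. **Migratory classification** — a multivariate Gaussian null is
   fitted (robustly) to all instantaneous velocities in the movie; each
   track's per-step squared Mahalanobis distance is referred to χ²(2),
   the minimum step p-value is Šidák-combined over the trace length,
   and tracks with p < α (default 0.01) are called migratory, split
   into dorsal vs ventral by net displacement.
7. **Domain scoring** — the spinal cord is divided into four equal
   dorsoventral sections: normalized depth u ∈ [0, 0.5) is dorsal,
   [0.5, 0.75) is pMN, [0.75, 1] is ventral; serial-section counts are
   summed into totals per 200 µm (10 × 20 µm sections).

## Worked example

Simulate a movie (20 cells: 15 near-stationary, 3 dorsal and 2 ventral
migrators at 1 µm/min; photobleaching, drift-free, 5% Gaussian noise)
and run the full pipeline:

```bash
opctrack simulate --out movie.tif --truth gt.csv --seed 5
opctrack run --movie movie.tif --out results --seed 5
```

which prints the per-movie migratory counts

```
{"total_migratory": 5, "dorsal": 3, "ventral": 2}
```

— all five simulated migrators recovered with the correct direction and
no stationary cell mislabelled. `results/summary.json` holds the
per-track statistics; the three largest net movers and two typical
stationary cells from this run:

```
{'track_id': 16, 'distance_um': 39.22, 'avg_speed_um_per_min': 1.006, 'net_dv_um': +39.04, 'duration_min': 39.0}
{'track_id': 6,  'distance_um': 39.17, 'avg_speed_um_per_min': 1.004, 'net_dv_um': -39.03, 'duration_min': 39.0}
{'track_id': 4,  'distance_um': 39.26, 'avg_speed_um_per_min': 1.007, 'net_dv_um': +39.02, 'duration_min': 39.0}
{'track_id': 2,  'distance_um': 5.96,  'avg_speed_um_per_min': 0.153, 'net_dv_um': +0.04,  'duration_min': 39.0}
{'track_id': 3,  'distance_um': 5.34,  'avg_speed_um_per_min': 0.137, 'net_dv_um': +0.18,  'duration_min': 39.0}
```

Migrators show avg speed ≈ 1 µm/min and |net dorsoventral
displacement| ≈ 39 µm over 39 min (the configured speed × duration);
stationary cells accumulate ~5–6 µm of jitter path length with
near-zero net displacement. Positive `net_dv_um` is dorsal.

Domain scoring from a positions table (`position` in the same units as
the annotated cord boundaries):

```bash
opctrack quantify --cells cells.csv --cord cord.json --out counts.json
# cells at normalized depths 0.10, 0.60, 0.90 ->
# {"dorsal": 1, "pmn": 1, "ventral": 1, "total": 3}
```

The library API mirrors the CLI: `opctrack.simulate.simulate_movie`,
`opctrack.preprocess.correct_photobleach` / `register_global`,
`opctrack.detect.detect_movie` / `enforce_temporal_consistency`,
`opctrack.track.track_movie` / `solve_tracks`,
`opctrack.motility.compute_motility`,
`opctrack.classify.classify_migratory`, `opctrack.domains.assign_domain`
and `opctrack.pipeline.run_pipeline`.

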