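# Methods

This note documents the models and procedures implemented in
`opctrack`, the parameters that matter, the numerical choices, and what
the synthetic-data tests do and do not demonstrate about real imaging.

## Synthetic movies and what they emulate

The generator (`opctrack.simulate`) renders lateral-view spinal-cord
movies: isotropic 2-D Gaussian blobs (SD `cell_sigma_px`, default 2 px)
over a uniform background, a dense band of near-stationary cells in the
ventral half of the field (the pMN domain), and a minority of cells
migrating dorsally or ventrally at constant speed. The dorsal axis is
decreasing row index (image "up"), used consistently everywhere.
Corruptions applied, all recorded in the ground truth:

- **Photobleaching** — a multiplicative factor `exp(-rate * t)` per
  frame (default rate 0.01/frame).
- **Drift** — a constant per-frame translation accumulated over time
  (default zero), standing in for larval growth.
- **Noise** — additive Gaussian with SD `noise_sd` (default 50, i.e.
  5% of the default blob amplitude 1000 over background 100; a 16-bit
  camera scale).
- **Jitter** — iid Gaussian positional jitter of every cell per frame
  (`jitter_sd_px`, default 0.15 px ≈ 0.1 µm/min velocity scale at the
  default calibration of 0.5 µm/px and 1 min/frame).

Cell motion is a constant-velocity directed walk plus jitter — the
simplest model sufficient for recovery testing; real OPCs pause, turn
and extend processes, none of which is simulated. Trajectories of
different cells keep a minimum same-frame separation of
max(8 px, 4σ), emulating the mutual exclusion of tiling cells; the
generator therefore does not exercise prolonged cell–cell contact,
occlusion, or division. Migratory cells are placed before stationary
ones so their full corridor can be cleared; an impossible request
(field too small) raises a configuration error rather than degrading.

Default acquisition values (0.5 µm/px, 1 min/frame, 40 frames,
128 × 128 px) are plausible for spinning-disc imaging of larval
zebrafish but are config-exposed, never hard-coded: real experiments
must set their own calibration.

Passing tests on these movies show the *algorithms* are correct and
calibrated under the stated corruptions; they do not certify
performance on real data with autofluorescence, z-projection artifacts,
morphologically complex cells, or cell division.

## Photobleaching correction

Each frame is mapped affinely to the whole-movie global mean and
variance: `out = (f - mean_f) * sd_global / sd_f + mean_global`. Any
fixed target is equivalent up to affine scale for downstream detection;
the global moments make the correction exactly idempotent. A
zero-variance frame is an error naming the frame index. Bleach
correction runs before registration (the reverse order would estimate
shifts between frames of very different brightness).

## Drift registration

Model: pure translation per frame against a reference (default frame
0), estimated by phase cross-correlation with upsampled subpixel
refinement (factor 50) and applied by linear resampling; out-of-field
pixels are filled with the frame median so edges cannot spawn phantom
detections. Linear (order-1) interpolation is chosen over cubic to
avoid ringing at blob edges.

A coherently migrating minority of cells biases a single correlation
pass: while their displacement still overlaps the static correlation
peak (within a few px), the subpixel peak blends the two motions and
the estimate is dragged by several tenths of a pixel — enough to
inject a common-mode velocity spike into every stationary track. The
estimator therefore makes a second pass: regions whose aligned
|difference| exceeds `max(median + 8 MAD-sigma, 0.25 × blob amplitude)`
are masked (filled with the median in both images) and the shift is
re-estimated from the static content. The amplitude-relative floor
prevents masking of mere interpolation residue in clean movies, and
masking is skipped when more than 30% of the field would be flagged
(as happens under pure noise, where the first pass is already
unbiased). Measured recovery error on synthetic drift of 0.3 px/frame
is ≪ 0.1 px RMS noise-free and ≈ 0.4–0.5 px RMS at noise equal to 20%
of the blob amplitude.

## Detection

Frames are transformed by the negated scale-normalized
Laplacian-of-Gaussian at scale `sigma_px` (input centred first so a
constant frame gives an exactly zero response). Candidate regions come
from a strictly decreasing threshold sweep on the response (default:
median + {10, 8, 6, 5, 4, 3} MAD-sigmas, falling back to the standard
deviation on noise-free frames); each local response maximum
contributes the connected component, within the area bounds
[`min_area_px`, `max_area_px`] = [5, 400], at the threshold maximizing
its significance. Significance is a pooled two-sample z between the
region's raw intensity and a 2-px-dilated boundary ring (pixels of
other regions excluded).

Because candidates sit at selected response maxima, their z is biased
upward even on pure noise (measured null location ≈ +2). The null is
therefore estimated empirically from *decoys*: the identical extraction
run on the negated response (dark blobs), whose mirrored z distribution
matches the candidates' selection bias. Robust location/scale
(median/MAD) of the pooled decoys define a normal null; the scale is
clipped to [1, 2] — a pooled two-sample z cannot have sub-unit null
dispersion, and a much larger spread indicates heterogeneous artifact
decoys (e.g. resampling sidelobes in noise-free movies), in which case
only the decoy location is trusted. One-sided p-values are corrected by
Benjamini–Hochberg: per movie in `detect_movie` (a lone noise candidate
then competes against the whole movie's candidate list, keeping the
realized false-positive rate well under the nominal α), per frame in
single-frame `detect_cells`. Survivors are kept greedily disjoint in
decreasing z (ties: larger area, then scan order).

Final centroids are refined by an iterated Gaussian-windowed centre of
mass (window σ = detection scale, 3 iterations) on
background-subtracted intensity, with pixels owned by neighbouring
detections excluded from the window. Plain pixel-set centroids have
heavy-tailed errors — region membership flickers with noise, and a
bright neighbour drags the estimate — which would corrupt the
chi-square calibration of the velocity test downstream; the windowed
estimator is continuous in the image values and empirically restores
the χ²(2) tail of standardized velocities.

### Temporal consistency

For every interior frame, merge proposals (two regions whose union is
matched by one region in both neighbour frames) and split proposals
(one region matched by two in both neighbours) are evaluated; within
each connected component of conflicting proposals the subset minimizing
the total `(1 − IoU)` cost against the original neighbour-frame
segmentations is chosen exhaustively (capped at 12 proposals per
component). Merges take pixel unions, splits partition pixels by
nearest reference centroid (the mean of the paired neighbour
centroids), so pixel mass is conserved; ties prefer the unmodified
input.

## Tracking

Linking is a min-cost node-disjoint path cover on a DAG: each detection
is a split node pair of capacity one carrying reward
`log((1-p_det)/p_det)` (default p_det = 0.98, i.e. −3.89), entry and
exit arcs cost `−log(p_birth)` each (default p_birth = 0.01), and
transition arcs between detections ≤ `max_gap_frames` (default 2)
apart cost the negative log of an isotropic Gaussian displacement
density with per-axis SD `σ_mode √gap` plus `gap_penalty` (default 1)
per skipped frame. Arcs beyond `cutoff_sigmas` (default 5) standard
deviations are omitted. Two regimes form the mixed motion model:
σ_normal (default 2 px) and σ_rapid (default 8 px); rapid arcs are
available only where the regional intensity-change test fires — the
mean frame difference in a square window (half-width 6 px) around a
detection, standardized against the whole-difference-frame median/MAD
with a √n window factor, exceeding |z| > 3. With these defaults a
track becomes profitable at roughly a dozen linked detections; for the
40-frame default movies every true cell forms one track, while isolated
spurious detections cannot pay their birth cost.

The solver is exact: successive shortest paths on the residual graph,
augmenting while the best source→sink path has negative cost. Shortest
paths use a label-correcting search (SPFA), which tolerates the
negative arc costs directly; the residual graph of a
successive-shortest-path flow never contains a negative cycle, so the
search terminates. Ties are broken by node index, making solutions
deterministic. Optimality is verified in the tests against exhaustive
enumeration of all node-disjoint path covers on small random instances.
Identity swaps at cell crossings are resolved exactly as the cost model
dictates: the solver returns the cheaper cover, which preserves
identity whenever the geometry makes swapping more expensive.

## Motility statistics

All statistics are 2-D (movies are projected lateral views; this is
fixed, not configurable). Distance traveled sums consecutive-point
displacement magnitudes (a gap contributes its straight-line chord);
instantaneous velocity divides each displacement by the actual elapsed
time; average speed is distance over total duration; net dorsoventral
displacement is `−Δrow × pixel_size`, positive dorsal. A track needs
two entries for any statistic (error otherwise). The migratory
direction call uses the sign of the net dorsoventral displacement with
a dead zone of `direction_threshold_um` (default 2 µm) reported as
`none`; the threshold is a free choice, config-exposed. "Average
speed" here always means distance/duration, not the magnitude of the
net displacement over duration; the two differ for curved paths.

## Migratory-cell classification

The velocity null is a single bivariate Gaussian fitted to all
instantaneous velocities of all tracks in the movie — resting on the
assumption that the large majority of cells are effectively
stationary, so the pooled velocity cloud is dominated by jitter and
localization noise. The default fit is robust: componentwise
median/MAD initialization followed by iterated trimming at the χ²(2)
0.975 Mahalanobis contour, with the trimmed covariance divided by the
exact Gaussian truncation factor `P(χ²₄ ≤ k)/P(χ²₂ ≤ k)` so the
estimate remains consistent under the null. The robust fit is the
default because the plain sample moments are masked by a coherent
minority of movers: with contamination fraction p, a mover's squared
Mahalanobis distance saturates near `(1−p)/p` (≈ 3 at 25% movers)
regardless of its speed, making fast cells undetectable exactly when
there are many of them. The naive fit remains available
(`robust=False`).

Each track is tested one-sidedly in speed: per-step d² against χ²(2),
trace p-value `1 − (1 − p_min)^m` (Šidák over the m steps), migratory
iff p < α (default 0.01). Velocities of consecutive steps share a
position and are negatively correlated, but at the extreme per-step
quantiles the combination operates on (~2.6 × 10⁻⁴ for m ≈ 39), Gaussian
exceedances are asymptotically independent and the measured type-I
error on 2 000 simulated stationary traces is statistically
indistinguishable from α. Tracks too short for a velocity are labelled
non-migratory with p = 1. The null is fitted per movie; pooling across
movies would require a shared noise scale the data do not guarantee.

## Domain scoring

Normalized depth `u = (position − dorsal_boundary) /
(ventral_boundary − dorsal_boundary)` divides the cord into four equal
sections with half-open edges toward dorsal: u ∈ [0, 0.5) dorsal (top
two sections), [0.5, 0.75) pMN (third section), [0.75, 1] ventral
(bottom quarter); u = 1 belongs to ventral so every in-cord position
has exactly one domain. Boundaries are user input (manual annotation),
not segmented from images. Serial-section counts are summed
elementwise; the reported span is `n_sections × thickness_um`
(default 10 × 20 µm = 200 µm).

## Determinism and problem sizes

All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning; identical config + seed gives
bit-identical movies and byte-identical summary JSON. The test battery
uses 40-frame 128 × 128 px movies with 20 cells, 100-frame noise
stacks for detector calibration, 2 000 traces for classifier
calibration, and ≤ 12-detection instances for the exhaustive flow
oracle — sizes chosen so the full verification runs in minutes on one
CPU while keeping every statistical check adequately powered.

## Known limitations

- Pure-translation registration only; rotation, scaling and nonrigid
  growth are out of scope.
- The detector is a simplified significance-scored threshold-sweep
  blob segmenter, not a reimplementation of an order-statistics
  component-tree detector; its contract (FDR-controlled, scored
  segmentation) is what downstream stages rely on.
- The tracker is a path cover: division and merging are not modelled.
- Classification uses velocity magnitude only; morphology or marker
  intensity play no role in distinguishing cell types.
- 2-D only; z-stacks must be projected upstream.
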