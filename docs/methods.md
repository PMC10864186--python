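# Methods

## Scope and model

`cafi` studies how much of a microscopy time-lapse can be reconstructed
after temporal downsampling, for scenes made of bright particle-like
structures. Everything is evaluated against simulated movies with exact
ground truth; the package contains the generator, the interpolators, the
metrics and the tracking/scoring machinery, wired into three benchmark
protocols.

## Particle-motion simulator

The generator emulates a "switching uniform" particle movie: `n_particles`
spots on a dark background, each switching per frame between a directed
step and a Brownian step.

* Mode: Bernoulli draw with probability `p_directed` per frame per
  particle. A directed step advances `base_speed` pixels along a
  persistent heading (a uniformly random unit vector); a Brownian step
  adds independent Gaussian displacements with per-axis standard
  deviation `sigma_brownian` pixels.
* Borders: positions are mirror-reflected into the field; only after a
  reflection is the heading re-randomized. Particle count is constant —
  no appearance, disappearance, fusion or fission.
* Rendering: each particle is an isotropic Gaussian of peak amplitude 1
  above `background`, with σ chosen so the full width at half maximum
  equals `diameter` (default 15 px, a lysosome-like size at high
  magnification). Profiles are truncated at 5σ (tail < 4·10⁻⁶).
* Noise: with finite `snr`, i.i.d. Gaussian noise of standard deviation
  amplitude/`snr` is added. Noise is never clipped in memory; clipping
  happens only when writing integer formats.

Defaults (the study conditions of all benchmarks): 128×128 px, 225
frames, 10 particles, diameter 15, `base_speed` 1 px/frame,
`p_directed` 0.9, `sigma_brownian` 0.3, dark background, noiseless.
The dense movie at 1 px/frame makes stride-*k* subsampling a
"velocity-*k*" condition: at most *k* px of directed travel between
consecutive kept frames. Mostly-directed motion (`p_directed` 0.9) with
a small Brownian component mimics transported organelles; purely
Brownian content is explicitly *not* what motion-compensated
interpolation can recover (a random walk between two observed frames is
unpredictable), and the parameter-recovery analysis covers the Brownian
regime separately. Ten 15-px spots on 128² leave the field sparse enough
that spots are usually, not always, well separated — occasional
encounters are part of the conditions.

Benchmark drivers multiply the rendered unit-amplitude movies by 255
before adding noise or detecting spots (the "8-bit intensity
convention"), so noise standard deviations (0–80) and detector
thresholds (5, 1.5) carry their customary meaning for 8-bit microscopy
data. Quality metrics are computed after global min-max normalization
(below), so this scale choice does not affect them.

## Interpolators

All interpolators insert one frame between each adjacent pair (2×); the
iterative driver applies 2× passes to reach 4×/8×/16×. Original frames
are preserved bit-exactly at anchor positions, and the operation is
axis-agnostic (time or depth along the leading axis).

* `none` — duplication of the earlier frame.
* `bil` — purely temporal linear blend at t = 0.5 (no spatial
  resampling).
* `bic` — per-pixel Catmull–Rom cubic through the four flanking frames
  (end frames replicated at sequence boundaries); exact for temporally
  linear and quadratic signals.
* `cafi` — motion-compensated interpolation, the package's core.

### Optical flow

`estimate_flow` is a two-level coarse-to-fine Gaussian pyramid around
iterative Lucas–Kanade estimation (window radius 12 px, 15 warp
iterations per level, pyramid downscale 2). The coarse level extends the
range to global translations beyond 10 px (measured mean endpoint error
≤ 0.02 px on smooth textures translated 3–12 px); the local data term
keeps flow anchored to image structure, so in featureless regions it
decays to zero instead of propagating spurious long-range motion — the
failure mode that makes globally regularized variational flow (TV-L1)
unreliable on sparse bright spots over dark background. Each level's
field is 5×5 median-filtered: least-squares flow develops isolated
outliers where the image gradient degenerates (e.g. exactly at a blob's
peak), and the median removes them without biasing smooth fields.
Constant images carry no motion information and yield zero flow with a
warning.

### Warping, consistency and the blend fallback

The midframe at time t ∈ (0,1) backward-warps each anchor along its
scaled flow with cubic-spline sampling (bilinear sampling measurably
low-passes smooth content at fractional offsets) and edge replication.
Reliability is quantified by forward–backward consistency: the
inconsistency e(p) = ‖F₀₁(p) + F₁₀(p + F₀₁(p))‖ maps to a weight
w = exp(−(e/s)²), s = 2 px by default, floored at 10⁻⁶. The combination

    c  = (1−t)·w₀ + t·w₁
    Î_t = (1−t)·w₀·warp(I₀) + t·w₁·warp(I₁) + (1−c)·[(1−t)·I₀ + t·I₁]

fills the missing confidence mass with the linear blend. This was a
deliberate design choice over renormalizing the two warp weights:
renormalization forces a choice between two warps even where *both* are
untrustworthy, and in those regions averaging two wrong warps is worse
than blending — with renormalization the content-aware method lost to
plain blending in mean SSIM on the particle benchmarks, with the
fallback it dominates blending at all tested velocities. Output is
clipped to the input intensity range to suppress spline overshoot.

## Quality metrics

SSIM uses the standard form: Gaussian window 11×11 with σ = 1.5,
stabilizers K₁ = 0.01, K₂ = 0.03, population (not sample) statistics,
data range L = 1. PSNR is 20·log₁₀(L/RMSE); identical frames give an
infinite PSNR that is excluded from means with a logged count. Before
metric computation both sequences are min-max normalized using the
*ground truth's* global range, so all methods are compared on one scale
and L = 1 is exact; whether to score all frames or only the held-out
(removed and re-synthesized) frames is a parameter, and the benchmarks
score held-out frames only — anchor frames are bit-exact by
construction and would only dilute differences.

## Tracking

Detection is single-scale scale-normalized Laplacian of Gaussian at
σ = d/(2√2) (the scale maximizing the normalized response for a Gaussian
blob of diameter d), local maxima above an absolute threshold, sub-pixel
refinement by separable parabolic fit of the 3×3 response neighborhood
(exact to ≲ 0.01 px for isolated spots). Linking solves, per consecutive
frame pair, the exact minimum-total-squared-distance assignment with
links forbidden beyond the gating distance; a second assignment stage
joins track ends to later starts (frame difference 2…`max_frame_gap`,
distance ≤ `gap_distance`). No merge/split events. Gates given in
physical units are converted through `pixel_size` when present;
otherwise they are pixels. Protocol defaults: diameter 10, threshold 5,
gates 25/25, max frame gap 2 (velocity benchmark); diameter 15,
threshold 1.5, gates 15/15, max frame gap 1 (noise benchmark).

## Track scoring

Estimated tracks are paired one-to-one with ground-truth tracks by exact
assignment under the gated distance d(θ, θ̂) = Σ min(‖p_t − p̂_t‖, ε)
over the union of the two tracks' detection frames (a frame covered by
only one of them costs ε); a ground-truth track may match a dummy at
cost |θ|·ε, and estimated tracks left unmatched are spurious. From the
optimal pairing: α = 1 − d/d₀ with d₀ = Σ|θ|·ε; β = (d₀ − d)/(d₀ +
Σ_spurious |θ̂|·ε) ≤ α; point Jaccard TP/(TP+FN+FP) with TP = paired
detections within ε; track Jaccard paired/(paired + dummy-matched +
spurious); localization RMSE over TP pairs. The gate defaults to
ε = 5 px (configurable). A paired track counts as correct for the track
Jaccard regardless of residual distance; with no TP pairs the
localization RMSE is reported as NaN. Segmentation is scored as mean
per-object IoU with optimal one-to-one object matching per frame
(unmatched objects contribute 0; a frame empty in both stacks counts 1
with a warning).

## Benchmark protocols

All drivers simulate one dense 225-frame movie from an explicit seed and
return long-form tables (protocol, method, level, metric, value, seed).

* **Velocity** — for v = 2…10: stride-v selection truncated to 17 frames
  forms the ground truth (image and track side alike); every second
  frame is removed and re-interpolated with each method; pixel metrics
  on the 8 held-out frames, tracking criteria against the 17-frame
  ground-truth tracks.
* **Iterative 16×** — the dense movie is reduced to its 15 stride-16
  anchors and re-interpolated back to 225 frames by four 2× passes.
  Quality is averaged per interpolated position (1…15 between anchors):
  the central position, synthesized in the first pass across the full
  16-frame gap, is the hardest and the per-position PSNR curve is
  U-shaped.
* **Noise** — Gaussian noise of std 0–80 (8-bit scale) is added to the
  velocity-5 ground truth; the noisy sequence is 2× downsampled and
  re-interpolated; metrics are computed against the *noisy* undownsampled
  ground truth, tracking with the noise-protocol settings against the
  exact simulator tracks.

Problem sizes (128² px, 10 particles, 9 velocities, 5 noise levels) were
chosen to make a full benchmark run a matter of minutes on a single CPU
while keeping ≥ 8 held-out frames per condition; α and the other
tracking statistics remain somewhat seed-dependent at this size, so
analyses that compare α across noise levels average a few consecutive
seeds.

## What the simulation does and does not show

The generator reproduces the geometry and kinetics that matter for
motion-compensated interpolation — spot size, directed-vs-Brownian
mixture, velocity scaling, SNR — but not photobleaching, motion blur,
depth-dependent PSFs, particle fusion/fission or visibility switching,
nor textured non-particulate structures (membranes, mitochondria
networks). Results transfer to real data only to the extent that the
scene is particle-like and the motion between consecutive frames stays
within the flow estimator's range (roughly the spot diameter); beyond
that the interpolator falls back to blending by construction, and purely
Brownian displacement is unrecoverable in principle.

## Numerical choices and degenerate inputs

* Flow on constant images: zero, with a warning; non-finite flow
  triggers an outright blend fallback.
* Weights are floored at 10⁻⁶ (keeps the weighted combination defined
  where the consistency kernel underflows).
* Interpolated frames are clipped to the observed input range.
* PSNR of identical frames: +inf, excluded from means with a count.
* IoU of two empty masks: 1, with a warning.
* Track scoring with empty ground truth: error (the criteria are
  undefined); empty estimates are valid (all-dummy matching).
* Assignment problems use `scipy.optimize.linear_sum_assignment` on
  gate-masked cost matrices with a large finite sentinel for forbidden
  links; solutions therefore maximize the number of admissible links
  first and minimize cost among those — matching LAP-tracker behavior.
* Catmull–Rom at sequence ends replicates the boundary frame.

## Limitations

* The flow estimator's range is bounded by its pyramid (two levels,
  radius 12): displacements much beyond ~25 px between anchors
  degenerate to the blend fallback.
* Detection is 2-D; volumetric movies are handled by maximum-intensity
  projection or per-slice processing, not true 3-D detection.
* The scoring gate ε and the dummy-cost convention are configurable
  because published challenge tooling is not fully specified; defaults
  follow the common ε = 5 px convention.
* TIFF I/O is plain multi-page grayscale; OME metadata and multichannel
  data are out of scope.
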