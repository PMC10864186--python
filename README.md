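# cafi — content-aware frame interpolation toolkit for microscopy time-lapses

Live-cell microscopy trades temporal resolution against phototoxicity and
photobleaching: imaging fast enough to resolve organelle dynamics often
damages the sample. One way out is to acquire sparsely and synthesize the
missing frames computationally. `cafi` implements and — just as
importantly — *evaluates* that idea end to end for particle-like
fluorescent structures (lysosomes, vesicles, spots):

* a seeded **particle-motion simulator** ("switching uniform" bright
  spots with mixed directed and Brownian motion) that produces movies
  together with exact ground-truth trajectories;
* **frame interpolators**: frame duplication (`none`), temporal linear
  blend (`bil`), temporal Catmull–Rom cubic (`bic`), and a
  motion-compensated content-aware interpolator (`cafi`) built on dense
  optical flow, bidirectional warping and flow-consistency weighting,
  applied iteratively for 2×–16× temporal upsampling (iCAFI), along
  either the time or the z axis;
* **pixel quality metrics** (SSIM, RMSE, PSNR, error maps, temporal
  color projections, green/magenta overlays);
* **spot tracking**: scale-normalized Laplacian-of-Gaussian detection
  with sub-pixel refinement and Simple-LAP linking with gap closing;
* the **five particle-tracking-challenge criteria** (α, β, point and
  track Jaccard, localization RMSE), segmentation IoU, and three
  reproducible benchmark drivers (velocity sweep, 16× iterative
  interpolation, noise sweep).

## The method in brief

Given two frames $I_0$ and $I_1$, the content-aware interpolator
estimates dense forward and backward optical flow $F_{0\to1}$,
$F_{1\to0}$ (coarse-to-fine iterative Lucas–Kanade), backward-warps each
frame halfway along its flow, and blends the warps with per-pixel
weights $w$ derived from forward–backward flow consistency,
$w = \exp(-\|F_{0\to1}(p) + F_{1\to0}(p + F_{0\to1}(p))\|^2/s^2)$:

$$\hat I_t = (1-t)\,w_0\,\mathcal{W}(I_0, -t F_{0\to1})
          + t\,w_1\,\mathcal{W}(I_1, -(1-t) F_{1\to0})
          + (1-c)\,[(1-t) I_0 + t I_1],\qquad c = (1-t)w_0 + t\,w_1 .$$

Where flow is reliable this is a pure motion-compensated blend; where it
is not (occlusions, motion beyond the estimator's range, featureless
background) the result degrades continuously to the plain linear blend.
Tracking quality is scored with the challenge criteria: ground-truth and
estimated tracks are paired by exact assignment under the gated distance
$d(\theta,\hat\theta) = \sum_t \min(\|p_t - \hat p_t\|, \varepsilon)$,
giving $\alpha = 1 - d(\Theta,\hat\Theta^*)/d(\Theta,\emptyset)$ and its
spurious-track-penalized variant β, plus detection-level Jaccard indices
and localization RMSE over true-positive pairs.

## Worked example

Simulate a dense movie, build the velocity-5 ground truth (every fifth
frame, 17 frames), drop every second frame, re-interpolate, and compare
blending with content-aware interpolation on the held-out frames:

```python
import numpy as np
from cafi import (
    SimulationConfig, simulate_particles, make_velocity_series,
    downsample_axis, held_out_frames, interpolate_sequence,
    quality_report, track, score_tracks, downsample_tracks,
)
from cafi.tracking import DetectionConfig, LinkConfig

cfg = SimulationConfig(n_frames=225, n_particles=10, diameter=15, seed=1)
dense, gt_tracks = simulate_particles(cfg)
dense = dense.with_frames(dense.frames * 255)          # 8-bit intensity scale

gt = make_velocity_series(dense, v=5)                  # 17-frame ground truth
gt_v5_tracks = downsample_tracks(gt_tracks, stride=5, max_frames=17)

anchors = downsample_axis(gt, stride=2)                # keep every 2nd frame
held, _ = held_out_frames(gt, stride=2)
for method in ("bil", "cafi"):
    recon = interpolate_sequence(anchors, method)
    q = quality_report(gt, recon, frames=held)
    est = track(recon, DetectionConfig(10, 5), LinkConfig(25, 25, 2))
    s = score_tracks(gt_v5_tracks, est, epsilon=5)
    print(f"{method:>4}: SSIM {q.means['ssim']:.3f}  RMSE {q.means['rmse']:.4f}  "
          f"PSNR {q.means['psnr']:.1f} dB  alpha {s.alpha:.3f}  "
          f"point-Jaccard {s.jsc_points:.3f}")
```

Output:

```
 bil: SSIM 0.936  RMSE 0.0242  PSNR 32.3 dB  alpha 0.675  point-Jaccard 0.765
cafi: SSIM 0.953  RMSE 0.0204  PSNR 33.9 dB  alpha 0.708  point-Jaccard 0.826
```

At five pixels of travel per frame the content-aware reconstruction is
both closer to the ground truth pixel-wise (higher SSIM/PSNR, lower
RMSE) and yields better downstream tracking (higher α and point
Jaccard) than blending, because blending renders each moving spot as two
half-intensity ghosts while motion compensation places one spot at its
interpolated position.

The same pipeline is available from the shell:

```sh
cafi simulate --seed 1 --out run/sim
cafi interpolate --method cafi --factor 2 --in run/sim/movie.tif --out run/interp
cafi track --in run/interp/interpolated.tif --out run/tracks
cafi score-tracks --gt run/sim/tracks.xml --est run/tracks/tracks.xml --out run/score
cafi benchmark velocity --seed 1 --out run/bench
```

Every command writes a `manifest.json` (parameters, seed, artifact
checksums) sufficient to re-run it identically.

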