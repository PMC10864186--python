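"""Tracking-challenge scoring, segmentation IoU and benchmark drivers.

Tracking criteria follow the particle-tracking-challenge definitions.
Estimated tracks are paired one-to-one with ground-truth tracks by an
exact assignment minimizing the gated track distance

    d(θ, θ̂) = Σ_t min(‖p_t − p̂_t‖, ε)

summed over the union of the two tracks' detection frames (a frame where
only one track has a detection costs ε); a ground-truth track may instead
be matched to a dummy at cost |θ|·ε. From the optimal pairing:

* α   = 1 − d(Θ, Θ̂*) / d(Θ, ∅), with d(Θ, ∅) = Σ_θ |θ|·ε
* β   = (d(Θ, ∅) − d(Θ, Θ̂*)) / (d(Θ, ∅) + Σ_spurious |θ̂|·ε)
* point Jaccard  = TP / (TP + FN + FP), TP = paired detections within ε
* track Jaccard  = paired / (paired + dummy-matched GT + spurious)
* localization RMSE over the TP pairs.

The three benchmark drivers reproduce the velocity, iterative-
interpolation and noise protocols on simulated movies and return
long-form result tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core_io import ImageSequence, LabelSequence, Track, TrackSet
from .interpolate import (
    downsample_axis,
    held_out_frames,
    icafi,
    interpolate_sequence,
    make_velocity_series,
)
from .metrics import MetricConfig, quality_report
from .simulate import SimulationConfig, add_gaussian_noise, simulate_particles
from .tracking import DetectionConfig, LinkConfig, track as run_tracker

__all__ = [
    "TrackingScore",
    "TrackMatching",
    "pair_tracks",
    "score_tracks",
    "downsample_tracks",
    "iou",
    "mean_matched_iou",
    "run_velocity_benchmark",
    "run_icafi_benchmark",
    "run_noise_benchmark",
    "INTENSITY_SCALE_8BIT",
]

# benchmark movies are placed on an 8-bit-like scale before noise addition
# and detection, so TrackMate-style thresholds keep their customary meaning
INTENSITY_SCALE_8BIT = 255.0

_FORBIDDEN = 1e15


@dataclass
class TrackingScore:
    """The five tracking criteria plus supporting counts."""

    alpha: float
    beta: float
    jsc_points: float
    jsc_tracks: float
    rmse_loc: float
    n_paired_tracks: int = 0
    n_unmatched_gt: int = 0
    n_spurious: int = 0
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "jsc_points": self.jsc_points,
            "jsc_tracks": self.jsc_tracks,
            "rmse_loc": self.rmse_loc,
        }


@dataclass
class TrackMatching:
    """Optimal GT↔estimate track pairing and its total gated distance."""

    pairs: list[tuple[int, int]]
    unmatched_gt: list[int]
    spurious_est: list[int]
    total_distance: float


def _track_distance(gt: Track, est: Track, epsilon: float) -> float:
    g = gt.as_dict()
    e = est.as_dict()
    frames = set(g) | set(e)
    d = 0.0
    for f in frames:
        if f in g and f in e:
            d += min(float(np.linalg.norm(g[f] - e[f])), epsilon)
        else:
            d += epsilon
    return d


def pair_tracks(gt: TrackSet, est: TrackSet, epsilon: float = 5.0) -> TrackMatching:
    """Optimal one-to-one pairing of estimated with ground-truth tracks.

    Solved exactly as a rectangular assignment: each GT track is matched
    either to an estimated track (cost = gated track distance) or to a
    dummy (cost |θ|·ε). Estimated tracks left unassigned are spurious.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(gt) == 0:
        raise ValueError("tracking criteria are undefined for empty ground truth")
    n_gt, n_est = len(gt), len(est)
    cost = np.full((n_gt, n_est + n_gt), _FORBIDDEN)
    for i, g in enumerate(gt):
        for j, e in enumerate(est):
            cost[i, j] = _track_distance(g, e, epsilon)
        cost[i, n_est + i] = len(g) * epsilon  # dummy
    rows, cols = linear_sum_assignment(cost)
    pairs, unmatched = [], []
    total = 0.0
    for i, j in zip(rows, cols):
        total += cost[i, j]
        if j < n_est:
            pairs.append((int(i), int(j)))
        else:
            unmatched.append(int(i))
    spurious = sorted(set(range(n_est)) - {j for _, j in pairs})
    return TrackMatching(pairs, unmatched, spurious, float(total))


def score_tracks(gt: TrackSet, est: TrackSet, epsilon: float = 5.0) -> TrackingScore:
    """Compute the five tracking criteria for an estimated track set."""
    matching = pair_tracks(gt, est, epsilon)
    d0 = float(sum(len(t) for t in gt) * epsilon)
    d = matching.total_distance
    spurious_cost = float(sum(len(est[j]) for j in matching.spurious_est) * epsilon)
    alpha = 1.0 - d / d0
    beta = (d0 - d) / (d0 + spurious_cost)
    tp = 0
    sq_dists: list[float] = []
    for i, j in matching.pairs:
        g = gt[i].as_dict()
        e = est[j].as_dict()
        for f in set(g) & set(e):
            dist = float(np.linalg.norm(g[f] - e[f]))
            if dist <= epsilon:
                tp += 1
                sq_dists.append(dist**2)
    fn = gt.n_detections - tp
    fp = est.n_detections - tp
    jsc_points = tp / (tp + fn + fp) if (tp + fn + fp) else 1.0
    n_pairs = len(matching.pairs)
    denom = n_pairs + len(matching.unmatched_gt) + len(matching.spurious_est)
    jsc_tracks = n_pairs / denom if denom else 1.0
    rmse_loc = float(np.sqrt(np.mean(sq_dists))) if sq_dists else float("nan")
    return TrackingScore(
        alpha=alpha,
        beta=beta,
        jsc_points=jsc_points,
        jsc_tracks=jsc_tracks,
        rmse_loc=rmse_loc,
        n_paired_tracks=n_pairs,
        n_unmatched_gt=len(matching.unmatched_gt),
        n_spurious=len(matching.spurious_est),
        tp=tp,
        fp=fp,
        fn=fn,
    )


def downsample_tracks(
    gt: TrackSet, stride: int, max_frames: int | None = None
) -> TrackSet:
    """Keep ground-truth detections at the same frames as a stride-k movie.

    Detections at frames 0, stride, 2·stride, … are kept and re-indexed
    to 0, 1, 2, …; with ``max_frames`` the result is truncated like the
    image-side velocity series. Tracks left without detections are dropped.
    ``stride`` 1 re-indexes trivially (identity).
    """
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    out = []
    for t in gt:
        keep = t.frames % stride == 0
        new_frames = t.frames[keep] // stride
        positions = t.positions[keep]
        if max_frames is not None:
            sel = new_frames < max_frames
            new_frames, positions = new_frames[sel], positions[sel]
        if len(new_frames):
            out.append(Track(track_id=t.track_id, frames=new_frames, positions=positions))
    return TrackSet(out)


# ---------------------------------------------------------------------------
# Segmentation overlap
# ---------------------------------------------------------------------------

def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B| of two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty: IoU defined as 1")
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mean_matched_iou(gt: LabelSequence, pred: LabelSequence) -> float:
    """Mean per-object IoU with optimal one-to-one object matching.

    Per frame, ground-truth and predicted objects are matched by maximal
    total IoU (exact assignment; zero-overlap matches are discarded);
    unmatched objects of either side contribute 0. The per-frame mean is
    taken over the union of objects, then averaged over frames.
    """
    if gt.masks.shape != pred.masks.shape:
        raise ValueError("label stacks must share one shape")
    frame_means = []
    for g, p in zip(gt.masks, pred.masks):
        g_labels = [l for l in np.unique(g) if l != 0]
        p_labels = [l for l in np.unique(p) if l != 0]
        if not g_labels and not p_labels:
            warnings.warn("frame with no objects in either stack: counted as 1")
            frame_means.append(1.0)
            continue
        if not g_labels or not p_labels:
            frame_means.append(0.0)
            continue
        iou_mat = np.zeros((len(g_labels), len(p_labels)))
        for i, gl in enumerate(g_labels):
            gm = g == gl
            for j, pl in enumerate(p_labels):
                pm = p == pl
                inter = np.logical_and(gm, pm).sum()
                if inter:
                    iou_mat[i, j] = inter / np.logical_or(gm, pm).sum()
        rows, cols = linear_sum_assignment(-iou_mat)
        matched = [(i, j) for i, j in zip(rows, cols) if iou_mat[i, j] > 0]
        total = sum(iou_mat[i, j] for i, j in matched)
        n_objects = len(g_labels) + len(p_labels) - len(matched)
        frame_means.append(total / n_objects)
    return float(np.mean(frame_means))


# ---------------------------------------------------------------------------
# Benchmark drivers
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ("protocol", "method", "level", "metric", "value", "seed")

_VELOCITY_DETECTION = DetectionConfig(diameter=10.0, threshold=5.0)
_VELOCITY_LINKING = LinkConfig(linking_distance=25.0, gap_distance=25.0, max_frame_gap=2)
_NOISE_DETECTION = DetectionConfig(diameter=15.0, threshold=1.5)
_NOISE_LINKING = LinkConfig(linking_distance=15.0, gap_distance=15.0, max_frame_gap=1)


def _reconstruct(anchors: ImageSequence, method: str, factor: int = 2) -> ImageSequence:
    return icafi(anchors, method=method, factor=factor)


def _rows(protocol, method, level, seed, metrics: dict[str, float]) -> list[dict]:
    return [
        {
            "protocol": protocol,
            "method": method,
            "level": level,
            "metric": k,
            "value": v,
            "seed": seed,
        }
        for k, v in metrics.items()
    ]


def run_velocity_benchmark(
    cfg: SimulationConfig | None = None,
    velocities: tuple[int, ...] = tuple(range(2, 11)),
    methods: tuple[str, ...] = ("none", "bil", "cafi"),
    seed: int = 0,
    epsilon: float = 5.0,
    max_frames: int = 17,
    with_tracking: bool = True,
) -> pd.DataFrame:
    """Velocity protocol: stride-v ground truth, 2× downsample, re-interpolate.

    One dense movie is simulated; for each velocity v the stride-v
    17-frame ground truth and its tracks are extracted, the ground truth
    is 2× temporally downsampled, re-interpolated with each method, and
    scored with pixel metrics on the held-out frames and (optionally)
    with the five tracking criteria against the downsampled ground-truth
    tracks.
    """
    cfg = replace(cfg or SimulationConfig(), seed=seed)
    dense, gt_tracks = simulate_particles(cfg)
    dense = dense.with_frames(dense.frames * INTENSITY_SCALE_8BIT)
    rows: list[dict] = []
    for v in velocities:
        gt_v = make_velocity_series(dense, v, max_frames=max_frames)
        tracks_v = downsample_tracks(gt_tracks, v, max_frames=max_frames)
        anchors = downsample_axis(gt_v, 2)
        held_idx, _ = held_out_frames(gt_v, 2)
        for method in methods:
            recon = _reconstruct(anchors, method)
            report = quality_report(gt_v, recon, frames=held_idx)
            rows += _rows("velocity", method, v, seed, report.means)
            if with_tracking:
                est = run_tracker(recon, _VELOCITY_DETECTION, _VELOCITY_LINKING)
                score = score_tracks(tracks_v, est, epsilon)
                rows += _rows("velocity", method, v, seed, score.as_dict())
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_icafi_benchmark(
    cfg: SimulationConfig | None = None,
    factor: int = 16,
    methods: tuple[str, ...] = ("none", "bil", "cafi"),
    seed: int = 0,
) -> pd.DataFrame:
    """Iterative-interpolation protocol: 16× downsample, then 16× re-upsample.

    The dense movie is reduced to its stride-``factor`` anchors and
    re-interpolated back to full length by iterated 2× interpolation.
    Quality is reported per interpolated position (1 … factor−1 between
    anchors, averaged over all anchor intervals): the central position,
    synthesized in the first iteration across the widest gap, shows the
    largest quality drop.
    """
    cfg = replace(cfg or SimulationConfig(), seed=seed)
    dense, _ = simulate_particles(cfg)
    dense = dense.with_frames(dense.frames * INTENSITY_SCALE_8BIT)
    usable = ((len(dense) - 1) // factor) * factor + 1
    dense = dense.with_frames(dense.frames[:usable])
    anchors = downsample_axis(dense, factor)
    rows: list[dict] = []
    for method in methods:
        recon = _reconstruct(anchors, method, factor=factor)
        assert len(recon) == len(dense)
        for pos in range(1, factor):
            idx = np.arange(pos, len(dense), factor)
            report = quality_report(dense, recon, frames=idx)
            rows += _rows("icafi", method, pos, seed, report.means)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_noise_benchmark(
    cfg: SimulationConfig | None = None,
    noise_stds: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0),
    methods: tuple[str, ...] = ("none", "bil", "cafi"),
    seed: int = 0,
    epsilon: float = 5.0,
    velocity: int = 5,
    max_frames: int = 17,
    with_tracking: bool = True,
) -> pd.DataFrame:
    """Noise protocol: corrupt the velocity-5 ground truth, downsample, re-interpolate.

    Gaussian noise of each standard deviation (8-bit intensity scale) is
    added to the velocity-5 ground-truth sequence; the noisy sequence is
    2× downsampled, re-interpolated, and compared with the noisy but
    undownsampled ground truth. Tracking uses the wider blob/lower
    threshold settings of the noise protocol.
    """
    cfg = replace(cfg or SimulationConfig(), seed=seed)
    dense, gt_tracks = simulate_particles(cfg)
    dense = dense.with_frames(dense.frames * INTENSITY_SCALE_8BIT)
    gt_v = make_velocity_series(dense, velocity, max_frames=max_frames)
    tracks_v = downsample_tracks(gt_tracks, velocity, max_frames=max_frames)
    noise_rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for std in noise_stds:
        noisy_gt = add_gaussian_noise(gt_v, std, seed=int(noise_rng.integers(2**31 - 1)))
        anchors = downsample_axis(noisy_gt, 2)
        held_idx, _ = held_out_frames(noisy_gt, 2)
        for method in methods:
            recon = _reconstruct(anchors, method)
            report = quality_report(noisy_gt, recon, frames=held_idx)
            rows += _rows("noise", method, std, seed, report.means)
            if with_tracking:
                est = run_tracker(recon, _NOISE_DETECTION, _NOISE_LINKING)
                score = score_tracks(tracks_v, est, epsilon)
                rows += _rows("noise", method, std, seed, score.as_dict())
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
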