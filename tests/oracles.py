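"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: metrics are
computed with explicit sliding-window double loops, and track scoring
enumerates every possible track assignment.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rmse_naive(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            total += (float(a[i, j]) - float(b[i, j])) ** 2
    return math.sqrt(total / (h * w))


def psnr_naive(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    err = rmse_naive(a, b)
    if err == 0:
        return float("inf")
    return 20.0 * math.log10(data_range / err)


def ssim_naive(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = 1.0,
    win: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Literal Gaussian-windowed SSIM over all fully valid window positions."""
    r = win // 2
    x = np.arange(-r, r + 1)
    k1d = np.exp(-0.5 * (x / sigma) ** 2)
    k1d /= k1d.sum()
    kern = np.outer(k1d, k1d)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    h, w = a.shape
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            wa = a[i - r : i + r + 1, j - r : j + r + 1]
            wb = b[i - r : i + r + 1, j - r : j + r + 1]
            mua = float((kern * wa).sum())
            mub = float((kern * wb).sum())
            va = float((kern * wa * wa).sum()) - mua**2
            vb = float((kern * wb * wb).sum()) - mub**2
            cab = float((kern * wa * wb).sum()) - mua * mub
            vals.append(
                ((2 * mua * mub + c1) * (2 * cab + c2))
                / ((mua**2 + mub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Exhaustive track scoring
# ---------------------------------------------------------------------------

def _track_dist(gt_track, est_track, epsilon: float) -> float:
    g = {int(f): p for f, p in zip(gt_track.frames, gt_track.positions)}
    e = {int(f): p for f, p in zip(est_track.frames, est_track.positions)}
    d = 0.0
    for f in set(g) | set(e):
        if f in g and f in e:
            d += min(math.dist(g[f], e[f]), epsilon)
        else:
            d += epsilon
    return d


def brute_force_score(gt, est, epsilon: float = 5.0) -> dict[str, float]:
    """Track criteria via exhaustive enumeration of all GT↔estimate pairings.

    Every injective mapping of GT tracks onto estimated tracks or dummies
    is enumerated; the minimum-total-distance mapping defines the scores.
    Feasible only for a handful of tracks.
    """
    n_gt, n_est = len(gt), len(est)
    dist = [[_track_dist(g, e, epsilon) for e in est] for g in gt]
    dummy = [len(g) * epsilon for g in gt]
    best = None
    # choices per gt track: est index or -1 (dummy); est indices must be distinct
    options = list(range(n_est)) + [-1]
    for combo in itertools.product(options, repeat=n_gt):
        used = [c for c in combo if c >= 0]
        if len(used) != len(set(used)):
            continue
        total = sum(
            dist[i][c] if c >= 0 else dummy[i] for i, c in enumerate(combo)
        )
        if best is None or total < best[0]:
            best = (total, combo)
    total, combo = best
    d0 = sum(dummy)
    pairs = [(i, c) for i, c in enumerate(combo) if c >= 0]
    spurious = sorted(set(range(n_est)) - {c for _, c in pairs})
    spurious_cost = sum(len(est[j]) * epsilon for j in spurious)
    tp = 0
    sq = []
    for i, j in pairs:
        g = {int(f): p for f, p in zip(gt[i].frames, gt[i].positions)}
        e = {int(f): p for f, p in zip(est[j].frames, est[j].positions)}
        for f in set(g) & set(e):
            dd = math.dist(g[f], e[f])
            if dd <= epsilon:
                tp += 1
                sq.append(dd**2)
    n_gt_points = sum(len(t) for t in gt)
    n_est_points = sum(len(t) for t in est)
    fn = n_gt_points - tp
    fp = n_est_points - tp
    return {
        "total_distance": total,
        "alpha": 1.0 - total / d0,
        "beta": (d0 - total) / (d0 + spurious_cost),
        "jsc_points": tp / (tp + fn + fp) if (tp + fn + fp) else 1.0,
        "jsc_tracks": len(pairs) / (len(pairs) + (n_gt - len(pairs)) + len(spurious)),
        "rmse_loc": math.sqrt(sum(sq) / len(sq)) if sq else float("nan"),
    }


def random_trackset(rng: np.random.Generator, max_tracks: int = 4, max_len: int = 10):
    """A random small TrackSet for oracle comparisons."""
    from cafi.core_io import Track, TrackSet

    n = int(rng.integers(1, max_tracks + 1))
    tracks = []
    for tid in range(n):
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, 4))
        frames = np.arange(start, start + length)
        positions = np.column_stack(
            [rng.uniform(0, 40, length), rng.uniform(0, 40, length), np.zeros(length)]
        )
        tracks.append(Track(track_id=tid, frames=frames, positions=positions))
    return TrackSet(tracks)
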