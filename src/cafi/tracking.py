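"""Spot detection and frame-to-frame linking (TrackMate-style Simple LAP).

Detection: scale-normalized Laplacian-of-Gaussian response at a single
scale matched to the expected blob diameter, local maxima above an
absolute threshold, sub-pixel refinement by separable quadratic fit of
the 3×3 response neighborhood.

Linking: per consecutive frame pair, a minimum-cost bipartite assignment
with squared-distance costs, links forbidden beyond the gating distance;
a second assignment stage joins track ends to later track starts across
small frame gaps (gap closing). No merge/split events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .core_io import ImageSequence, Track, TrackSet

__all__ = [
    "Spot",
    "DetectionConfig",
    "LinkConfig",
    "detect_spots_log",
    "link_frames",
    "close_gaps",
    "track",
]

_FORBIDDEN = 1e12  # cost sentinel for gated-out links


@dataclass
class Spot:
    """A detection: frame index, sub-pixel position and LoG response."""

    frame: int
    x: float
    y: float
    quality: float


@dataclass
class DetectionConfig:
    """LoG detector settings (defaults follow the simulated-movie protocol)."""

    diameter: float = 10.0
    threshold: float = 5.0

    @property
    def sigma(self) -> float:
        """LoG scale maximizing the normalized response for a blob of ``diameter``."""
        return self.diameter / (2.0 * np.sqrt(2.0))


@dataclass
class LinkConfig:
    """Simple-LAP linking gates.

    Distances are in pixels, or in physical units when the sequence
    carries a ``pixel_size`` (they are divided by it before gating).
    ``max_frame_gap`` is the largest frame difference bridged by gap
    closing; values < 2 disable gap closing.
    """

    linking_distance: float = 25.0
    gap_distance: float = 25.0
    max_frame_gap: int = 2

    def validate(self) -> None:
        if self.linking_distance <= 0 or self.gap_distance <= 0:
            raise ValueError("distance gates must be positive")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be ≥ 0")


def _subpixel_offset(patch: np.ndarray) -> tuple[float, float]:
    """Parabolic peak refinement on a 3×3 response patch → (dx, dy) in (−0.5, 0.5)."""
    c = patch[1, 1]
    dx = dy = 0.0
    denom_x = patch[1, 0] - 2.0 * c + patch[1, 2]
    if denom_x < 0:
        dx = 0.5 * (patch[1, 0] - patch[1, 2]) / denom_x
    denom_y = patch[0, 1] - 2.0 * c + patch[2, 1]
    if denom_y < 0:
        dy = 0.5 * (patch[0, 1] - patch[2, 1]) / denom_y
    return float(np.clip(dx, -0.5, 0.5)), float(np.clip(dy, -0.5, 0.5))


def detect_spots_log(
    seq: ImageSequence,
    diameter: float = 10.0,
    threshold: float = 5.0,
) -> list[list[Spot]]:
    """Detect bright blobs in every frame.

    Returns one spot list per frame. The response is the negated
    scale-normalized LoG, ``−σ²·ΔG_σ * I`` with ``σ = diameter/(2√2)``,
    which peaks at ≈ half the blob amplitude for a matched Gaussian blob.
    """
    if diameter <= 2:
        raise ValueError("diameter must exceed 2 px")
    sigma = DetectionConfig(diameter, threshold).sigma
    out: list[list[Spot]] = []
    for f, frame in enumerate(np.asarray(seq.frames, dtype=float)):
        resp = -(sigma**2) * gaussian_laplace(frame, sigma)
        peaks = peak_local_max(
            resp, min_distance=1, threshold_abs=threshold, exclude_border=False
        )
        spots = []
        for r, c in peaks:
            dx = dy = 0.0
            if 0 < r < resp.shape[0] - 1 and 0 < c < resp.shape[1] - 1:
                dx, dy = _subpixel_offset(resp[r - 1 : r + 2, c - 1 : c + 2])
            spots.append(Spot(frame=f, x=c + dx, y=r + dy, quality=float(resp[r, c])))
        out.append(spots)
    return out


def _gated_assignment(
    cost: np.ndarray, gate_sq: float
) -> list[tuple[int, int]]:
    """Minimum-cost assignment; pairs with cost above the squared gate are dropped."""
    if cost.size == 0:
        return []
    masked = np.where(cost <= gate_sq, cost, _FORBIDDEN)
    rows, cols = linear_sum_assignment(masked)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if masked[i, j] < _FORBIDDEN]


def link_frames(spots: list[list[Spot]], cfg: LinkConfig | None = None) -> TrackSet:
    """Link detections of consecutive frames into gapless tracks.

    Per frame pair, the minimum-total-squared-distance assignment is
    solved exactly; links longer than ``linking_distance`` are forbidden.
    Unassigned detections terminate or start tracks.
    """
    cfg = cfg or LinkConfig()
    cfg.validate()
    gate_sq = cfg.linking_distance**2
    # each active track: (list of Spot), keyed by index
    tracks: list[list[Spot]] = []
    active: dict[int, int] = {}  # spot index in current frame -> track index
    for f, frame_spots in enumerate(spots):
        if f == 0:
            active = {}
            for j, s in enumerate(frame_spots):
                tracks.append([s])
                active[j] = len(tracks) - 1
            continue
        prev_spots = spots[f - 1]
        prev_active = active
        active = {}
        if prev_spots and frame_spots:
            prev_xy = np.array([[s.x, s.y] for s in prev_spots])
            cur_xy = np.array([[s.x, s.y] for s in frame_spots])
            cost = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(axis=2)
            pairs = _gated_assignment(cost, gate_sq)
        else:
            pairs = []
        linked_cur = set()
        for i, j in pairs:
            if i in prev_active:
                ti = prev_active[i]
                tracks[ti].append(frame_spots[j])
                active[j] = ti
                linked_cur.add(j)
        for j, s in enumerate(frame_spots):
            if j not in linked_cur:
                tracks.append([s])
                active[j] = len(tracks) - 1
    return _to_trackset(tracks)


def _to_trackset(spot_lists: list[list[Spot]]) -> TrackSet:
    out = []
    for tid, spots in enumerate(spot_lists):
        spots = sorted(spots, key=lambda s: s.frame)
        out.append(
            Track(
                track_id=tid,
                frames=np.array([s.frame for s in spots]),
                positions=np.array([[s.x, s.y, 0.0] for s in spots]),
            )
        )
    return TrackSet(out)


def close_gaps(tracks: TrackSet, cfg: LinkConfig | None = None) -> TrackSet:
    """Join track ends to later track starts across short gaps.

    Candidate joins need a frame difference Δf with ``2 ≤ Δf ≤
    max_frame_gap`` and an end-to-start distance within ``gap_distance``;
    the minimum-total-squared-distance set of joins is chosen by exact
    assignment. Joined tracks keep no interpolated detections for the
    missing frames.
    """
    cfg = cfg or LinkConfig()
    cfg.validate()
    segs = [
        {"frames": list(t.frames), "positions": [p.copy() for p in t.positions]}
        for t in tracks
    ]
    if cfg.max_frame_gap < 2 or len(segs) < 2:
        return _segs_to_trackset(segs)
    n = len(segs)
    cost = np.full((n, n), _FORBIDDEN)
    for i, end_seg in enumerate(segs):
        ef, ep = end_seg["frames"][-1], end_seg["positions"][-1]
        for j, start_seg in enumerate(segs):
            if i == j:
                continue
            sf, sp = start_seg["frames"][0], start_seg["positions"][0]
            df = sf - ef
            if 2 <= df <= cfg.max_frame_gap:
                d2 = float(((np.asarray(ep)[:2] - np.asarray(sp)[:2]) ** 2).sum())
                if d2 <= cfg.gap_distance**2:
                    cost[i, j] = d2
    pairs = _gated_assignment(cost, cfg.gap_distance**2)
    # merge chains: successor[i] = j means segment j continues segment i
    successor = dict(pairs)
    has_pred = set(successor.values())
    merged: list[dict] = []
    for i in range(n):
        if i in has_pred:
            continue
        frames, positions = [], []
        k: int | None = i
        while k is not None:
            frames.extend(segs[k]["frames"])
            positions.extend(segs[k]["positions"])
            k = successor.get(k)
        merged.append({"frames": frames, "positions": positions})
    return _segs_to_trackset(merged)


def _segs_to_trackset(segs: list[dict]) -> TrackSet:
    return TrackSet(
        [
            Track(
                track_id=tid,
                frames=np.asarray(s["frames"]),
                positions=np.asarray(s["positions"]),
            )
            for tid, s in enumerate(segs)
        ]
    )


def track(
    seq: ImageSequence,
    detection: DetectionConfig | None = None,
    linking: LinkConfig | None = None,
) -> TrackSet:
    """Full pipeline: LoG detection → frame linking → gap closing.

    When the sequence carries a ``pixel_size``, linking gates given in
    physical units are converted to pixels first.
    """
    detection = detection or DetectionConfig()
    linking = linking or LinkConfig()
    if seq.pixel_size:
        linking = LinkConfig(
            linking_distance=linking.linking_distance / seq.pixel_size,
            gap_distance=linking.gap_distance / seq.pixel_size,
            max_frame_gap=linking.max_frame_gap,
        )
    spots = detect_spots_log(seq, detection.diameter, detection.threshold)
    return close_gaps(link_frames(spots, linking), linking)
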