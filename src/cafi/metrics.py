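"""Pixel-based image-quality metrics (SSIM, RMSE, PSNR) and comparison views.

Metrics are computed on globally min-max-normalized intensities (data
range 1.0) so every interpolation method is compared on one scale; the
normalization reference is the ground-truth sequence. SSIM follows the
standard Wang et al. form: 11×11 Gaussian window (σ = 1.5), stabilizers
K1 = 0.01 and K2 = 0.03, population statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.metrics import structural_similarity

from .core_io import ImageSequence, normalize_sequence

__all__ = [
    "MetricConfig",
    "QualityReport",
    "rmse",
    "psnr",
    "ssim",
    "rse_map",
    "quality_report",
    "temporal_color_projection",
    "overlay_comparison",
]


@dataclass
class MetricConfig:
    """Parameters of the pixel metrics.

    ``data_range`` is the dynamic range L of the compared images (1.0
    after min-max normalization). The SSIM window is Gaussian of size
    ``win_size`` (odd) with standard deviation ``sigma``.
    """

    data_range: float = 1.0
    win_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03

    def validate(self) -> None:
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.win_size % 2 != 1 or self.win_size < 3:
            raise ValueError("win_size must be an odd integer ≥ 3")


@dataclass
class QualityReport:
    """Per-frame and aggregate SSIM/RMSE/PSNR of a predicted sequence."""

    per_frame: pd.DataFrame  # columns: frame, ssim, rmse, psnr
    ssim_maps: list[np.ndarray] | None = None
    rse_maps: list[np.ndarray] | None = None
    n_infinite_psnr: int = 0

    @property
    def means(self) -> dict[str, float]:
        """Arithmetic means; infinite PSNR frames are excluded from the PSNR mean."""
        finite_psnr = self.per_frame["psnr"][np.isfinite(self.per_frame["psnr"])]
        return {
            "ssim": float(self.per_frame["ssim"].mean()),
            "rmse": float(self.per_frame["rmse"].mean()),
            "psnr": float(finite_psnr.mean()) if len(finite_psnr) else float("inf"),
        }


def _pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error ``sqrt(mean((a−b)²))``."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a: np.ndarray, b: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio ``20·log10(L / RMSE)`` in dB.

    Identical frames return ``inf``; aggregation excludes such frames
    from means (with a logged count).
    """
    cfg = cfg or MetricConfig()
    err = rmse(a, b)
    if err == 0.0:
        return float("inf")
    return float(20.0 * np.log10(cfg.data_range / err))


def ssim(
    a: np.ndarray, b: np.ndarray, cfg: MetricConfig | None = None
) -> tuple[float, np.ndarray]:
    """Mean structural similarity and the local SSIM map.

    Luminance·contrast·structure with C1 = (K1·L)² and C2 = (K2·L)²,
    averaged over a Gaussian-weighted sliding window.
    """
    cfg = cfg or MetricConfig()
    cfg.validate()
    a, b = _pair(a, b)
    if min(a.shape) < cfg.win_size:
        raise ValueError("frames smaller than the SSIM window")
    value, smap = structural_similarity(
        a,
        b,
        win_size=cfg.win_size,
        gaussian_weights=True,
        sigma=cfg.sigma,
        K1=cfg.k1,
        K2=cfg.k2,
        data_range=cfg.data_range,
        use_sample_covariance=False,
        full=True,
    )
    return float(value), smap


def rse_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel root squared error ``|a − b|`` (symmetric in a, b)."""
    a, b = _pair(a, b)
    return np.abs(a - b)


def quality_report(
    gt: ImageSequence,
    pred: ImageSequence,
    frames: np.ndarray | list[int] | None = None,
    cfg: MetricConfig | None = None,
    normalize: bool = True,
    keep_maps: bool = False,
) -> QualityReport:
    """Score a predicted sequence against ground truth, frame by frame.

    ``frames`` restricts scoring to a subset of indices (e.g. only the
    held-out frames of a downsample/re-interpolate protocol); ``None``
    scores every frame. With ``normalize`` both sequences are min-max
    normalized using the ground truth's global range, so the metric data
    range is 1.
    """
    cfg = cfg or MetricConfig()
    if len(gt) != len(pred):
        raise ValueError("ground truth and prediction must have equal length")
    if normalize:
        lo, hi = float(gt.frames.min()), float(gt.frames.max())
        gt = normalize_sequence(gt, "minmax_global")
        pred = normalize_sequence(pred, "minmax_global", ref_range=(lo, hi))
    idx = np.arange(len(gt)) if frames is None else np.asarray(frames, dtype=int)
    if len(idx) and (idx.min() < 0 or idx.max() >= len(gt)):
        raise ValueError("frame selection out of range")
    rows = []
    smaps: list[np.ndarray] = []
    rmaps: list[np.ndarray] = []
    n_inf = 0
    for i in idx:
        a, b = gt.frames[i], pred.frames[i]
        s, smap = ssim(a, b, cfg)
        p = psnr(a, b, cfg)
        if not np.isfinite(p):
            n_inf += 1
        rows.append({"frame": int(i), "ssim": s, "rmse": rmse(a, b), "psnr": p})
        if keep_maps:
            smaps.append(smap)
            rmaps.append(rse_map(a, b))
    if n_inf:
        warnings.warn(f"{n_inf} frame(s) with infinite PSNR excluded from the mean")
    return QualityReport(
        per_frame=pd.DataFrame(rows, columns=["frame", "ssim", "rmse", "psnr"]),
        ssim_maps=smaps if keep_maps else None,
        rse_maps=rmaps if keep_maps else None,
        n_infinite_psnr=n_inf,
    )


# ---------------------------------------------------------------------------
# Visualizations
# ---------------------------------------------------------------------------

def temporal_color_projection(seq: ImageSequence, cmap: str = "viridis") -> np.ndarray:
    """Project a sequence to one RGB image, color-coding time.

    Each frame is tinted with a perceptually ordered colormap position
    ``i/(T−1)`` and the tinted frames are combined by per-pixel maximum,
    so a moving structure traces a hue gradient along its trajectory.
    """
    frames = normalize_sequence(seq, "minmax_global").frames
    n = len(frames)
    cm = colormaps[cmap]
    out = np.zeros(frames.shape[1:] + (3,))
    for i, frame in enumerate(frames):
        tint = np.asarray(cm(i / (n - 1) if n > 1 else 0.0))[:3]
        out = np.maximum(out, frame[..., None] * tint[None, None, :])
    return out


def overlay_comparison(gt_seq: ImageSequence, pred_seq: ImageSequence) -> np.ndarray:
    """Green/magenta overlay of ground truth versus prediction.

    Green channel carries the temporal max-projection of the ground
    truth, red and blue the prediction's, so coinciding structures appear
    white/gray, ground-truth-only structures green and prediction-only
    magenta.
    """
    if gt_seq.frames.shape != pred_seq.frames.shape:
        raise ValueError("sequences must share one shape")
    g = normalize_sequence(gt_seq, "minmax_global").frames.max(axis=0)
    m = normalize_sequence(pred_seq, "minmax_global").frames.max(axis=0)
    return np.stack([m, g, m], axis=-1)
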