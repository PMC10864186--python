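"""Data model and I/O for microscopy image sequences and particle tracks.

Conventions used throughout the package:

* frame indices are 0-based;
* ``x`` is the column coordinate, ``y`` the row coordinate, both in pixels;
* subpixel positions refer to pixel centers (an object at ``x=3.0`` peaks in
  column 3);
* image stacks are stored ``T×H×W`` (or ``T×Z×H×W`` for volumes) and written
  as multi-page grayscale TIFF without OME metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

__all__ = [
    "FormatError",
    "TrackParseError",
    "ImageSequence",
    "VolumeSequence",
    "Track",
    "TrackSet",
    "LabelSequence",
    "read_image_stack",
    "write_image_stack",
    "read_isbi_xml",
    "write_isbi_xml",
    "read_tracks_table",
    "write_tracks_table",
    "max_project_z",
    "normalize_sequence",
]

TRACK_TABLE_COLUMNS = ("track_id", "frame", "x", "y", "z")


class FormatError(ValueError):
    """Raised when an image file does not match the expected grayscale layout."""


class TrackParseError(ValueError):
    """Raised when a track file is malformed or misses required fields."""


@dataclass
class ImageSequence:
    """An ordered stack of 2-D grayscale frames.

    Parameters
    ----------
    frames:
        ``T×H×W`` array of finite intensities. The leading axis is the
        sequence axis and may run along time or depth (``axis_label``).
    pixel_size:
        Physical size of one pixel (µm), optional.
    frame_interval:
        Time between frames (s), optional.
    axis_label:
        ``"t"`` or ``"z"``; which physical axis the leading axis represents.
    """

    frames: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None
    axis_label: str = "t"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite intensities")
        if self.axis_label not in ("t", "z"):
            raise ValueError(f"axis_label must be 't' or 'z', got {self.axis_label!r}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray) -> "ImageSequence":
        """A copy of this sequence with new pixel data and same metadata."""
        return replace(self, frames=frames)


@dataclass
class VolumeSequence:
    """A time series of z-stacks, stored ``T×Z×H×W``."""

    frames: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None
    z_spacing: float | None = None
    axis_label: str = "t"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be T×Z×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1 or self.frames.shape[1] < 1:
            raise ValueError("volume sequence needs T ≥ 1 and Z ≥ 1")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite intensities")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class Track:
    """One particle trajectory: detections ordered by strictly increasing frame."""

    track_id: int
    frames: np.ndarray  # (N,) int
    positions: np.ndarray  # (N, 3) float, columns x, y, z

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.frames.ndim != 1 or len(self.frames) < 1:
            raise ValueError("a track needs at least one detection")
        if self.positions.shape != (len(self.frames), 3):
            raise ValueError("positions must be (N, 3) matching frames")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices within a track must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("frame indices must be non-negative")
        if not np.isfinite(self.positions).all():
            raise ValueError("track positions must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    def as_dict(self) -> dict[int, np.ndarray]:
        """Map frame index → (x, y, z) position."""
        return {int(f): p for f, p in zip(self.frames, self.positions)}


@dataclass
class TrackSet:
    """A collection of trajectories (ground truth or tracker output)."""

    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def n_detections(self) -> int:
        return sum(len(t) for t in self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, p in zip(t.frames, t.positions):
                rows.append((t.track_id, int(f), p[0], p[1], p[2]))
        return pd.DataFrame(rows, columns=list(TRACK_TABLE_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise TrackParseError(f"track table missing columns: {missing}")
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            tracks.append(
                Track(
                    track_id=int(tid),
                    frames=grp["frame"].to_numpy(dtype=int),
                    positions=grp[["x", "y", "z"]].to_numpy(dtype=float),
                )
            )
        return cls(tracks)


@dataclass
class LabelSequence:
    """A stack of integer-labeled masks (0 = background, k > 0 = object k)."""

    masks: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(f"masks must be T×H×W, got shape {self.masks.shape}")
        if not np.issubdtype(self.masks.dtype, np.integer):
            raise ValueError("masks must be integer-valued")
        if self.masks.min() < 0:
            raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return self.masks.shape[0]


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_image_stack(path: str | Path) -> ImageSequence | VolumeSequence:
    """Read a grayscale multi-page TIFF as an image or volume sequence.

    A 2-D file becomes a length-1 sequence, a 3-D file is interpreted as
    ``T×Y×X`` and a 4-D file as ``T×Z×Y×X``. RGB files are rejected.
    Integer samples are kept as-is (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            data = series.asarray()
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read {path} as a TIFF stack: {exc}") from exc
    if "S" in axes or "C" in axes:
        raise FormatError(f"{path}: RGB/multi-channel TIFF not supported (axes {axes})")
    if data.ndim == 2:
        return ImageSequence(frames=data[None])
    if data.ndim == 3:
        return ImageSequence(frames=data)
    if data.ndim == 4:
        return VolumeSequence(frames=data)
    raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")


def write_image_stack(
    seq: ImageSequence | VolumeSequence,
    path: str | Path,
    dtype_policy: str = "preserve",
) -> None:
    """Write a sequence as a multi-page grayscale TIFF.

    ``dtype_policy="preserve"`` writes the array dtype untouched so that
    values round-trip exactly; ``"float32"`` and ``"uint16"`` convert
    (uint16 clips to the representable range).
    """
    if str(path) == "":
        raise ValueError("empty output path")
    data = seq.frames
    if not np.isfinite(data).all():
        raise ValueError("refusing to write non-finite intensities")
    if dtype_policy == "preserve":
        pass
    elif dtype_policy == "float32":
        data = data.astype(np.float32)
    elif dtype_policy == "uint16":
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    tifffile.imwrite(path, data, photometric="minisblack")


# ---------------------------------------------------------------------------
# ISBI challenge track XML
# ---------------------------------------------------------------------------

def read_isbi_xml(path: str | Path) -> TrackSet:
    """Read tracks from the ISBI 2012 particle-tracking-challenge XML dialect.

    Expected layout: a root element containing ``<particle>`` elements,
    each holding ``<detection t x y z>`` children. Track identifiers are
    assigned sequentially in document order (the dialect carries none).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrackParseError(f"malformed XML in {path}: {exc}") from exc
    tracks: list[Track] = []
    for tid, particle in enumerate(tree.getroot().iter("particle")):
        frames, positions = [], []
        for det in particle.iter("detection"):
            vals = []
            for attr in ("t", "x", "y", "z"):
                raw = det.get(attr)
                if raw is None:
                    raise TrackParseError(
                        f"{path}: <detection> in particle {tid} missing attribute {attr!r}"
                    )
                try:
                    vals.append(float(raw))
                except ValueError as exc:
                    raise TrackParseError(
                        f"{path}: non-numeric attribute {attr}={raw!r} in particle {tid}"
                    ) from exc
            frames.append(int(round(vals[0])))
            positions.append(vals[1:])
        if not frames:
            continue
        order = np.argsort(frames)
        tracks.append(
            Track(
                track_id=tid,
                frames=np.asarray(frames)[order],
                positions=np.asarray(positions)[order],
            )
        )
    return TrackSet(tracks)


def write_isbi_xml(tracks: TrackSet, path: str | Path) -> None:
    """Write a TrackSet in the ISBI challenge XML dialect.

    The ``z`` attribute is always written (0.0 for planar data) so one
    dialect covers 2-D and 3-D tracks. Float attributes use shortest
    round-tripping decimal representation, so write→read is lossless.
    """
    root = etree.Element("root")
    contest = etree.SubElement(root, "TrackContestISBI2012")
    for t in tracks:
        particle = etree.SubElement(contest, "particle")
        for f, p in zip(t.frames, t.positions):
            etree.SubElement(
                particle,
                "detection",
                t=str(int(f)),
                x=repr(float(p[0])),
                y=repr(float(p[1])),
                z=repr(float(p[2])),
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Tabular tracks
# ---------------------------------------------------------------------------

def read_tracks_table(path: str | Path) -> TrackSet:
    """Read tracks from a tab-separated table with columns track_id, frame, x, y, z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return TrackSet([])
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "z"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TrackParseError(f"{path}: non-numeric values in column {col!r}") from exc
    return TrackSet.from_dataframe(df)


def write_tracks_table(tracks: TrackSet, path: str | Path) -> None:
    tracks.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def max_project_z(vol: VolumeSequence) -> ImageSequence:
    """Maximum-intensity projection along z, yielding a 2-D + t sequence."""
    return ImageSequence(
        frames=vol.frames.max(axis=1),
        pixel_size=vol.pixel_size,
        frame_interval=vol.frame_interval,
        axis_label=vol.axis_label,
    )


def normalize_sequence(
    seq: ImageSequence,
    mode: str = "minmax_global",
    ref_range: tuple[float, float] | None = None,
) -> ImageSequence:
    """Rescale intensities for metric computation.

    ``minmax_global`` maps the global minimum to 0 and maximum to 1. When
    ``ref_range`` is given, that (min, max) is used instead of the
    sequence's own — this is how a prediction is placed on the ground
    truth's scale so both are compared over one data range. Constant input
    maps to all zeros with a warning. ``none`` returns the data unchanged
    as floats.
    """
    frames = np.asarray(seq.frames, dtype=float)
    if mode == "none":
        return seq.with_frames(frames)
    if mode != "minmax_global":
        raise ValueError(f"unknown normalization mode {mode!r}")
    lo, hi = ref_range if ref_range is not None else (frames.min(), frames.max())
    if hi <= lo:
        warnings.warn("constant sequence: normalization maps all intensities to 0")
        return seq.with_frames(np.zeros_like(frames))
    return seq.with_frames((frames - lo) / (hi - lo))
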