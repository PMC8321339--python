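"""Frame-stack loading, ROI cropping, scene partition and annotation I/O.

A video is represented as a :class:`FrameStack`: a ``(T, H, W)`` float array
of luminance values in ``[0, 255]`` together with its frame rate and the
1-based index of its first frame in the original numbering.  Image-sequence
directories (the convention of CASME II-style micro-expression datasets:
one image per frame, lexicographically ordered) and standard video
containers are both supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameStack",
    "ROISpec",
    "SceneSegment",
    "MEAnnotation",
    "load_frames",
    "save_frames",
    "load_annotations",
    "crop_roi",
    "partition_scenes",
]

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

# Rec.601 luma weights for RGB -> luminance conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FrameStack:
    """Ordered grayscale frames with a frame rate and a 1-based time origin."""

    frames: np.ndarray  # (T, H, W) float, luminance in [0, 255]
    fps: float
    t0: int = 1

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame values must be finite")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def t_index(self) -> np.ndarray:
        """1-based frame numbers in the original video's numbering."""
        return np.arange(self.t0, self.t0 + self.n_frames)

    def slice_time(self, start: int, end: int) -> "FrameStack":
        """Sub-stack for local (1-based, inclusive) frame numbers [start, end]."""
        if not (1 <= start <= end <= self.n_frames):
            raise ValueError(f"[{start}, {end}] outside [1, {self.n_frames}]")
        return replace(
            self,
            frames=self.frames[start - 1 : end],
            t0=self.t0 + start - 1,
        )


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular region of interest, 0-based top-left corner."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI corner must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "ROISpec":
        """Parse an ``x0,y0,width,height`` string (the CLI format)."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected x0,y0,width,height, got {text!r}")
        return cls(*parts)


@dataclass(frozen=True)
class SceneSegment:
    """A stationary scene, 1-based inclusive frame interval within a stack."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MEAnnotation:
    """Ground-truth onset/apex/offset of one micro-expression.

    ``N`` is the maximal expected micro-expression length in frames at the
    clip's frame rate (64 at 200 fps, 8 at 25 fps); ``N/2`` is the tolerance
    used by the correctness criterion.
    """

    sequence_id: str
    onset: int
    offset: int
    fps: float
    apex: Optional[int] = None
    N: int = field(default=0)

    def __post_init__(self) -> None:
        if self.N == 0:
            from .evaluation import default_N

            object.__setattr__(self, "N", default_N(self.fps))
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.apex is not None:
            if not (self.onset <= self.apex <= self.offset):
                raise ValueError(
                    f"sequence {self.sequence_id!r}: need onset <= apex <= offset, "
                    f"got {self.onset}, {self.apex}, {self.offset}"
                )
        elif self.onset > self.offset:
            raise ValueError(
                f"sequence {self.sequence_id!r}: onset {self.onset} > offset {self.offset}"
            )


def _to_luminance(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., :3] @ _LUMA_WEIGHTS
    raise ValueError(f"cannot interpret image of shape {img.shape} as a frame")


def load_frames(
    source: os.PathLike | str,
    kind: str = "image_dir",
    as_gray: bool = True,
    fps: Optional[float] = None,
) -> FrameStack:
    """Load a :class:`FrameStack` from an image-sequence directory or a video file.

    Parameters
    ----------
    source
        Directory of per-frame images (``kind="image_dir"``, lexicographic
        order) or a video container (``kind="video_file"``).
    as_gray
        Color frames are reduced to luminance with Rec.601 weights.
    fps
        Required for image directories; for video files it defaults to the
        container metadata.
    """
    import imageio.v2 as iio

    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"input source does not exist: {source}")

    if kind == "image_dir":
        if fps is None:
            raise ValueError("fps is required when loading an image directory")
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
        )
        if len(paths) < 2:
            raise ValueError(f"{source}: need at least 2 image files, found {len(paths)}")
        frames = []
        for p in paths:
            try:
                img = iio.imread(p)
            except Exception as exc:  # noqa: BLE001 - wrap decoder errors
                raise ValueError(f"unreadable image {p}: {exc}") from exc
            frames.append(_to_luminance(img) if as_gray else np.asarray(img, float))
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"{source}: inconsistent frame shapes {sorted(shapes)}")
        return FrameStack(np.stack(frames), fps=fps)

    if kind == "video_file":
        try:
            reader = iio.get_reader(source)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"cannot decode video {source}: {exc}") from exc
        meta = reader.get_meta_data()
        fps = fps or meta.get("fps")
        if fps is None:
            raise ValueError(f"{source}: container reports no fps; pass fps explicitly")
        frames = [_to_luminance(frame) if as_gray else np.asarray(frame, float)
                  for frame in reader]
        reader.close()
        if len(frames) < 2:
            raise ValueError(f"{source}: fewer than 2 decodable frames")
        return FrameStack(np.stack(frames), fps=float(fps))

    raise ValueError(f"unknown source kind {kind!r}")


def save_frames(stack: FrameStack, directory: os.PathLike | str) -> Path:
    """Write a stack as a zero-padded PNG image sequence (load_frames inverse)."""
    import imageio.v2 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digits = max(5, len(str(stack.n_frames)))
    for i, frame in enumerate(stack.frames, start=1):
        quantized = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{i:0{digits}d}.png", quantized)
    return directory


def load_annotations(path: os.PathLike | str) -> list[MEAnnotation]:
    """Load a CSV of onset/apex/offset annotations.

    Expected header: ``sequence_id,onset,apex,offset,fps[,N]`` — apex and N
    may be empty; N defaults from the frame rate.
    """
    df = pd.read_csv(path)
    required = {"sequence_id", "onset", "offset", "fps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")

    annotations = []
    for i, row in df.iterrows():
        apex = row.get("apex")
        apex = None if pd.isna(apex) else int(apex)
        n = row.get("N")
        n = 0 if (n is None or pd.isna(n)) else int(n)
        try:
            ann = MEAnnotation(
                sequence_id=str(row["sequence_id"]),
                onset=int(row["onset"]),
                offset=int(row["offset"]),
                fps=float(row["fps"]),
                apex=apex,
                N=n,
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: {exc}") from exc
        annotations.append(ann)
    return annotations


def crop_roi(stack: FrameStack, roi: ROISpec) -> FrameStack:
    """Restrict every frame to the rectangle ``roi``; the time axis is untouched."""
    height, width = stack.frame_shape
    if roi.x0 + roi.width > width or roi.y0 + roi.height > height:
        raise ValueError(
            f"ROI {roi} exceeds frame bounds {width}x{height} (WxH)"
        )
    return replace(
        stack,
        frames=stack.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width],
    )


def partition_scenes(
    stack: FrameStack,
    cut_threshold: float = 0.1,
    user_cuts: Optional[Sequence[int]] = None,
) -> list[SceneSegment]:
    """Partition a stack into stationary scenes (1-based, inclusive segments).

    A cut is declared between consecutive frames whose mean absolute
    luminance difference, normalized by the 255 range, exceeds
    ``cut_threshold``.  An explicit ``user_cuts`` list (frame numbers that
    start a new segment) takes precedence over the detector.  A static video
    yields a single segment covering the whole stack.
    """
    T = stack.n_frames
    if user_cuts is not None:
        cuts = list(user_cuts)
        if any(c2 <= c1 for c1, c2 in zip(cuts, cuts[1:])):
            raise ValueError("user_cuts must be strictly increasing")
        if any(not (2 <= c <= T) for c in cuts):
            raise ValueError(f"user_cuts must lie in [2, {T}]")
    else:
        if not (0 < cut_threshold <= 1):
            raise ValueError("cut_threshold must be in (0, 1]")
        diffs = np.abs(np.diff(stack.frames, axis=0)).mean(axis=(1, 2)) / 255.0
        cuts = [int(i) + 2 for i in np.nonzero(diffs > cut_threshold)[0]]

    bounds = [1, *cuts, T + 1]
    return [SceneSegment(a, b - 1) for a, b in zip(bounds, bounds[1:])]
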