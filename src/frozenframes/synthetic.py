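"""Ground-truthed synthetic clips for exercising the frozen-frame pipeline.

Each clip is a static background plus a face-surrogate blob whose interior
carries a fixed smooth texture.  Three time-varying ingredients emulate the
phenomenology of concealed micro-expressions:

* **plateaus** — exactly-frozen intervals: the pose is held bit-identically
  (before noise) and the blob's overall contrast relaxes a few percent, the
  way a deliberately concealed face relaxes to a flat neutral pose.  This
  makes plateaus local minima of the sigma_F energy, as frozen poses are in
  real footage;
* **bursts** — micro-expression surrogates: a short, smoothly windowed
  episode in which the blob interior is translated sub-pixel (bilinear
  resampling) and a localized deformation patch raises spatial contrast;
* **nuisances** — per-frame additive Gaussian noise and a slow global
  luminance drift, neither of which should move the detected minima.

All randomness flows from the spec's seed; there are no unseeded entry
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .evaluation import default_N
from .video_io import FrameStack, MEAnnotation

__all__ = [
    "BlobSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_sequence",
    "smooth_clip",
    "make_benchmark",
]

#: fractional contrast relaxation of the blob during a concealed plateau
PLATEAU_RELAXATION = 0.08
#: frames over which contrast ramps into / out of a plateau (outside it)
RAMP_FRAMES = 3


@dataclass(frozen=True)
class BlobSpec:
    """Face-surrogate parameters: center (y, x), radius and contrast
    (peak luminance above background)."""

    center: tuple[float, float] = (32.0, 32.0)
    radius: float = 18.0
    contrast: float = 70.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic clip.

    ``bursts`` are ``(start, end, amplitude, displacement)`` tuples with
    1-based inclusive frame intervals, ``amplitude`` the peak luminance of
    the deformation patch and ``displacement`` the peak translation in
    pixels.  ``plateaus`` are 1-based inclusive ``(start, end)`` intervals,
    pairwise disjoint and disjoint from bursts.  In ``exact_freeze`` mode
    the additive noise is suppressed inside plateaus so plateau frames are
    bit-identical.
    """

    T: int = 120
    fps: float = 25.0
    frame_shape: tuple[int, int] = (64, 64)
    blob: BlobSpec = field(default_factory=BlobSpec)
    bursts: tuple[tuple[int, int, float, float], ...] = ()
    plateaus: tuple[tuple[int, int], ...] = ()
    noise_std: float = 0.0
    drift_rate: float = 0.0
    seed: int = 0
    exact_freeze: bool = False

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        for s, e, *_ in self.bursts:
            if not (1 <= s <= e <= self.T):
                raise ValueError(f"burst [{s}, {e}] outside [1, {self.T}]")
        spans = sorted((s, e) for s, e, *_ in self.bursts)
        for s, e in self.plateaus:
            if not (1 <= s <= e <= self.T):
                raise ValueError(f"plateau [{s}, {e}] outside [1, {self.T}]")
            for bs, be, *_ in self.bursts:
                if s <= be and bs <= e:
                    raise ValueError(
                        f"plateau [{s}, {e}] overlaps burst [{bs}, {be}]"
                    )
        plat = sorted(self.plateaus)
        for (s1, e1), (s2, e2) in zip(plat, plat[1:]):
            if s2 <= e1:
                raise ValueError("plateaus must be pairwise disjoint")
        del spans


@dataclass(frozen=True)
class GroundTruth:
    """Planted event locations of a synthetic clip (1-based, inclusive)."""

    bursts: tuple[tuple[int, int], ...]
    plateaus: tuple[tuple[int, int], ...]
    still: np.ndarray  # per-frame stillness flag, shape (T,)

    def burst_boundaries(self) -> list[int]:
        """Onset and offset frames of every planted burst."""
        return [t for s, e in self.bursts for t in (s, e)]


def _raised_cosine(length: int) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 window over `length` samples (sin^2 profile)."""
    return np.sin(np.pi * (np.arange(length) + 0.5) / length) ** 2


def _blob_pattern(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Blob bump plus a fixed smooth interior texture (zero outside)."""
    H, W = spec.frame_shape
    y, x = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = spec.blob.center
    r2 = ((y - cy) ** 2 + (x - cx) ** 2) / spec.blob.radius**2
    bump = np.exp(-0.5 * r2 * 4.0)  # smooth support of ~radius
    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), 2.5)
    texture /= max(texture.std(), 1e-12)
    return spec.blob.contrast * bump * (1.0 + 0.35 * texture)


def _tension_profile(spec: SyntheticSpec) -> np.ndarray:
    """Per-frame contrast multiplier: 1 at baseline, relaxed inside plateaus,
    cosine ramps over RAMP_FRAMES just outside them (plateau frames stay
    bit-identical)."""
    tension = np.ones(spec.T)
    low = 1.0 - PLATEAU_RELAXATION
    for s, e in spec.plateaus:
        tension[s - 1 : e] = low
        for k in range(1, RAMP_FRAMES + 1):  # ramps outside [s, e]
            level = low + (1.0 - low) * 0.5 * (1 - np.cos(np.pi * k / (RAMP_FRAMES + 1)))
            i = s - 1 - k
            if 0 <= i < spec.T:
                tension[i] = min(tension[i], level)
            j = e - 1 + k
            if 0 <= j < spec.T:
                tension[j] = min(tension[j], level)
    return tension


def generate_sequence(spec: SyntheticSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a clip from its spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_shape
    y, x = np.mgrid[0:H, 0:W].astype(np.float64)

    background = 90.0 + 10.0 * (x / max(W - 1, 1))  # mild fixed gradient
    pattern = _blob_pattern(spec, rng)
    tension = _tension_profile(spec)

    # per-burst deformation patch: localized contrast-raising bump inside
    # the blob, a crease/dimple surrogate
    patches = []
    for s, e, amplitude, displacement in spec.bursts:
        cy = spec.blob.center[0] + rng.uniform(-0.4, 0.4) * spec.blob.radius
        cx = spec.blob.center[1] + rng.uniform(-0.4, 0.4) * spec.blob.radius
        patch = np.exp(-0.5 * (((y - cy) ** 2 + (x - cx) ** 2) / 4.0**2))
        angle = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(angle), np.cos(angle)])
        patches.append((s, e, amplitude, displacement, patch, direction))

    frames = np.empty((spec.T, H, W))
    plateau_mask = np.zeros(spec.T, dtype=bool)
    for s, e in spec.plateaus:
        plateau_mask[s - 1 : e] = True

    for t in range(1, spec.T + 1):
        shift = np.zeros(2)
        deform = np.zeros((H, W))
        for s, e, amplitude, displacement, patch, direction in patches:
            if s <= t <= e:
                w = _raised_cosine(e - s + 1)[t - s]
                shift += displacement * w * direction
                deform += amplitude * w * patch
        blob = pattern * tension[t - 1]
        if np.any(shift != 0.0):
            blob = ndimage.shift(blob, shift, order=1, mode="nearest")
        frame = background + blob + deform + spec.drift_rate * t
        if spec.noise_std > 0 and not (spec.exact_freeze and plateau_mask[t - 1]):
            frame = frame + rng.standard_normal((H, W)) * spec.noise_std
        elif spec.noise_std > 0:
            rng.standard_normal((H, W))  # keep the stream aligned across modes
        frames[t - 1] = frame

    # frames stay float; quantization/clamping happens only when written to
    # image files, so drift and noise never saturate the analysis values
    stack = FrameStack(frames, fps=spec.fps)
    truth = GroundTruth(
        bursts=tuple((s, e) for s, e, *_ in spec.bursts),
        plateaus=tuple(spec.plateaus),
        still=plateau_mask,
    )
    return stack, truth


def smooth_clip(
    seed: int,
    T: int = 200,
    frame_shape: tuple[int, int] = (32, 32),
    n_extrema: int = 3,
    fps: float = 25.0,
) -> FrameStack:
    """A band-limited clip for numerical checks of the minima/zeros duality.

    The clip is ``background + A(t) * P(x, y)`` with a fixed smooth random
    pattern ``P`` and a smooth positive amplitude envelope ``A``: the only
    temporal change is the envelope, so sigma_F is a smooth function of the
    filtered envelope and every one of its strict local minima sits where
    the temporal derivative — hence sigma_G — vanishes.  The envelope's
    band limit is kept well below the frame rate (a handful of extrema over
    hundreds of frames) so the discretely sampled sigma_G is an honest
    stand-in for its continuous-time counterpart.
    """
    rng = np.random.default_rng(seed)
    H, W = frame_shape
    background = 100.0 + ndimage.gaussian_filter(
        rng.standard_normal((H, W)), 4.0
    ) * 20.0
    pattern = ndimage.gaussian_filter(rng.standard_normal((H, W)), 2.0)
    pattern /= max(pattern.std(), 1e-12)

    t = np.arange(T) / T
    envelope = np.zeros(T)
    for _ in range(n_extrema):
        envelope += rng.uniform(0.3, 1.0) * np.cos(
            2 * np.pi * (rng.uniform(0.5, float(n_extrema)) * t + rng.uniform())
        )
    envelope = 1.5 + envelope / max(np.abs(envelope).max(), 1e-12)  # in [0.5, 2.5]

    frames = background[np.newaxis] + 15.0 * envelope[:, np.newaxis, np.newaxis] * pattern
    return FrameStack(frames, fps=fps)


def make_benchmark(
    n_clips: int,
    seed: int,
    fps: float = 25.0,
    noise_std: float = 2.0,
    frame_shape: tuple[int, int] = (64, 64),
    exact_freeze: bool = False,
) -> list[tuple[FrameStack, GroundTruth, MEAnnotation]]:
    """Seeded benchmark of clips with planted bursts flanked by frozen plateaus.

    Each clip carries one annotated burst (and, with probability 0.3, a
    second one, recorded in the ground truth) flanked by a frozen plateau
    before, after, or on both sides — mirroring the ways concealment
    brackets a real micro-expression.  Plateaus sit directly against the
    burst boundary and are no longer than ``N/2`` frames, so every frozen
    frame lies within the radius at which a detection counts as correct;
    bursts are short (well under ``N``), as micro-expressions are.
    Deterministic given ``seed``.
    """
    if n_clips < 1:
        raise ValueError("n_clips >= 1 required")
    rng = np.random.default_rng(seed)
    N = default_N(fps)
    scale = fps / 25.0  # temporal unit: frames per "standard" frame

    out = []
    for i in range(n_clips):
        T = int(rng.integers(round(100 * scale), round(150 * scale) + 1))
        n_bursts = 1 + int(rng.random() < 0.3)
        bursts: list[tuple[int, int, float, float]] = []
        plateaus: list[tuple[int, int]] = []
        # 0 before, 1 after, 2 both: concealment most often brackets the event
        # or follows it (the offset phase), and only sometimes precedes it only
        flank_choices = rng.choice(3, size=n_bursts, p=[0.2, 0.3, 0.5])
        # place bursts left to right with generous spacing
        cursor = int(round(12 * scale))
        for b in range(n_bursts):
            plat_len = int(rng.integers(max(2, round(0.375 * N)), max(2, round(0.5 * N)) + 1))
            burst_len = int(rng.integers(max(2, round(0.375 * N)), max(3, round(0.625 * N)) + 1))
            start = cursor + int(rng.integers(0, round(10 * scale) + 1)) + plat_len
            end = start + burst_len - 1
            if end + plat_len + round(12 * scale) > T:
                break
            amplitude = rng.uniform(15.0, 25.0)
            displacement = rng.uniform(0.5, 1.0)
            bursts.append((start, end, amplitude, displacement))
            flank = flank_choices[b]
            if flank in (0, 2):
                plateaus.append((start - plat_len, start - 1))
            if flank in (1, 2):
                plateaus.append((end + 1, end + plat_len))
            cursor = end + plat_len + int(round(15 * scale))
        if not bursts:  # clip too short for the drawn layout; plant one centrally
            plat_len = max(2, round(0.45 * N))
            start = T // 2
            end = min(T - plat_len - 1, start + max(2, round(0.5 * N)) - 1)
            bursts = [(start, end, 20.0, 0.8)]
            plateaus = [(start - plat_len, start - 1)]

        spec = SyntheticSpec(
            T=T,
            fps=fps,
            frame_shape=frame_shape,
            bursts=tuple(bursts),
            plateaus=tuple(plateaus),
            noise_std=noise_std,
            drift_rate=float(rng.uniform(0.0, 0.1)),
            seed=int(rng.integers(0, 2**31 - 1)),
            exact_freeze=exact_freeze,
        )
        stack, truth = generate_sequence(spec)
        onset, offset = truth.bursts[0]
        ann = MEAnnotation(
            sequence_id=f"clip_{i:03d}",
            onset=onset,
            offset=offset,
            fps=fps,
            N=N,
        )
        out.append((stack, truth, ann))
    return out
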