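"""Separable spatio-temporal filters for motion-energy analysis.

The motion-energy view of early vision models a motion-sensitive cell as a
separable spatio-temporal filter: a spatial low-pass kernel rho(x, y)
multiplied by a temporal kernel.  Two temporal kernels matter here:

* ``phi`` — a temporal *low-pass* (unit DC gain), giving the LL pair
  ``l(x, y, t) = rho(x, y) * phi(t)``;
* ``psi`` — a temporal *high-pass* defined as the derivative of phi,
  ``psi = d phi / dt`` (zero DC gain), giving the LH pair
  ``h(x, y, t) = rho(x, y) * psi(t)``.

With psi the derivative of phi, local minima of the spatial standard
deviation of the LL response mark frames where the LH response — the
motion signal — vanishes: frozen frames.  The classic biphasic temporal
kernel of the Adelson–Bergen model is also provided for reference
energy plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .video_io import FrameStack

__all__ = [
    "SeparableSTFilter",
    "BiphasicParams",
    "make_spatial_gaussian",
    "make_temporal_lowpass",
    "make_temporal_highpass",
    "make_biphasic",
    "make_filter_pair",
    "apply_separable",
    "default_temporal_size",
]

#: spatial Gaussian std (pixels) matching ~1 degree of visual angle on
#: full-resolution face videos
DEFAULT_RHO_STD = 9.0
DEFAULT_TRUNCATE = 3.0


def default_temporal_size(fps: float) -> int:
    """Default temporal low-pass length (frames) from the frame rate.

    The preattentive visual channel integrates roughly 13 images per second,
    so the support scales with the frame rate: 2 frames at 25 fps, 8 at
    200 fps (``max(2, round(fps / 25))``).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    return max(2, round(fps / 25))


def make_spatial_gaussian(rho_std: float, truncate: float = DEFAULT_TRUNCATE) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel, odd-sized, normalized to unit sum.

    The grid half-width is ``ceil(truncate * rho_std)`` so the kernel loses
    <0.3% of its mass before renormalization at the default truncation.
    """
    if rho_std <= 0:
        raise ValueError(f"rho_std must be positive, got {rho_std}")
    half = math.ceil(truncate * rho_std)
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-0.5 * (x / rho_std) ** 2)
    g1 /= g1.sum()
    return np.outer(g1, g1)


def _gaussian_taps(size: int) -> np.ndarray:
    # Gaussian with std = size/4 sampled on `size` taps centered on its mean.
    x = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-0.5 * (x / (size / 4.0)) ** 2)
    return g / g.sum()


def make_temporal_lowpass(kind: str = "box", size: int = 2) -> np.ndarray:
    """Temporal low-pass kernel phi with unit DC gain.

    ``box`` gives `size` uniform taps (a moving average); ``gaussian`` a
    Gaussian of std ``size/4`` truncated to `size` taps.
    """
    if size < 2:
        raise ValueError(f"temporal size must be >= 2, got {size}")
    if kind == "box":
        return np.full(size, 1.0 / size)
    if kind == "gaussian":
        return _gaussian_taps(size)
    raise ValueError(f"unknown temporal kernel kind {kind!r}")


def make_temporal_highpass(phi: np.ndarray) -> np.ndarray:
    """Discrete derivative psi = d phi / dt of a temporal low-pass kernel.

    Central differences on the zero-extended kernel:
    ``psi_i = (phi_{i+1} - phi_{i-1}) / 2`` with phi taken as 0 outside its
    support.  For a symmetric phi (box or Gaussian) the taps telescope and
    psi sums to 0 exactly; e.g. phi = [1/2, 1/2] yields psi = [1/4, -1/4].
    """
    phi = np.asarray(phi, dtype=np.float64)
    if phi.ndim != 1 or phi.size < 2:
        raise ValueError("phi must be a 1-D kernel with >= 2 taps")
    padded = np.concatenate([[0.0], phi, [0.0]])
    return (padded[2:] - padded[:-2]) / 2.0


@dataclass(frozen=True)
class BiphasicParams:
    """Order ``n``, rate ``k`` (1/frames) and support half-width of the
    classic biphasic temporal kernel."""

    n: int = 3
    k: float = 1.0
    support: float = 10.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.support < self.n / self.k:
            raise ValueError("support must be >= n/k (cover the positive lobe)")


def make_biphasic(params: BiphasicParams = BiphasicParams()) -> np.ndarray:
    """Biphasic temporal kernel (kt)^n e^(-kt) [1/n! - (kt)^2/(n+2)!].

    Sampled at integer t in [0, 2*support] and mean-subtracted so the kernel
    has zero DC gain; one positive lobe followed by one negative lobe, with
    the sign change of the raw response at ``kt = sqrt((n+2)!/n!)``.
    """
    n, k = params.n, params.k
    t = np.arange(0, int(round(2 * params.support)) + 1, dtype=np.float64)
    kt = k * t
    raw = kt**n * np.exp(-kt) * (1.0 / math.factorial(n) - kt**2 / math.factorial(n + 2))
    return raw - raw.mean()


@dataclass(frozen=True)
class SeparableSTFilter:
    """A separable spatio-temporal filter: spatial kernel rho times a temporal
    kernel, phi (mode ``"LL"``) or its derivative psi (mode ``"LH"``)."""

    rho: np.ndarray
    phi: np.ndarray
    mode: str = "LL"
    psi: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: 1-D factor of rho when the spatial kernel is separable (fast path)
    rho_1d: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("LL", "LH"):
            raise ValueError(f"mode must be 'LL' or 'LH', got {self.mode!r}")
        rho = np.asarray(self.rho, dtype=np.float64)
        phi = np.asarray(self.phi, dtype=np.float64)
        psi = make_temporal_highpass(phi) if self.psi is None else np.asarray(self.psi, float)
        if phi.size < 2:
            raise ValueError("temporal kernel must have size >= 2")
        if not np.all(np.isfinite(rho)) or not np.all(np.isfinite(phi)):
            raise ValueError("kernels must be finite")
        if abs(rho.sum() - 1.0) > 1e-9:
            raise ValueError("spatial kernel must have unit DC gain")
        if abs(phi.sum() - 1.0) > 1e-9:
            raise ValueError("temporal low-pass must have unit DC gain")
        if abs(psi.sum()) > 1e-9:
            raise ValueError("temporal high-pass must have zero DC gain")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)

    @property
    def temporal(self) -> np.ndarray:
        """The temporal kernel selected by ``mode``."""
        return self.phi if self.mode == "LL" else self.psi

    def as_mode(self, mode: str) -> "SeparableSTFilter":
        return replace(self, mode=mode)


def make_filter_pair(
    rho_std: float = DEFAULT_RHO_STD,
    phi_kind: str = "box",
    phi_size: int = 2,
    truncate: float = DEFAULT_TRUNCATE,
) -> tuple[SeparableSTFilter, SeparableSTFilter]:
    """Construct the matched (LL, LH) pair sharing rho, with psi = d phi/dt."""
    rho = make_spatial_gaussian(rho_std, truncate)
    half = math.ceil(truncate * rho_std)
    x = np.arange(-half, half + 1, dtype=np.float64)
    rho_1d = np.exp(-0.5 * (x / rho_std) ** 2)
    rho_1d /= rho_1d.sum()
    phi = make_temporal_lowpass(phi_kind, phi_size)
    ll = SeparableSTFilter(rho=rho, phi=phi, mode="LL", rho_1d=rho_1d)
    return ll, ll.as_mode("LH")


def apply_separable(stack: FrameStack, filt: SeparableSTFilter) -> FrameStack:
    """Convolve a stack with a separable spatio-temporal filter.

    Spatial 2-D convolution with rho, then temporal 1-D convolution with phi
    or psi depending on the filter mode; reflect padding on every axis, so
    the output has the shape of the input.  By separability the two stages
    commute.
    """
    if stack.n_frames < filt.temporal.size:
        raise ValueError(
            f"stack of {stack.n_frames} frames is shorter than the temporal "
            f"kernel (size {filt.temporal.size})"
        )
    frames = stack.frames
    if filt.rho_1d is not None:
        out = ndimage.convolve1d(frames, filt.rho_1d, axis=1, mode="reflect")
        out = ndimage.convolve1d(out, filt.rho_1d, axis=2, mode="reflect")
    else:
        out = ndimage.convolve(frames, filt.rho[np.newaxis, :, :], mode="reflect")
    out = ndimage.convolve1d(out, filt.temporal, axis=0, mode="reflect")
    return replace(stack, frames=out)
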