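"""Per-frame spatial-standard-deviation energy signals.

For a filtered sequence ``U(x, y, t)`` the temporal energy is

    sigma_U(t) = sqrt( (1/|Omega|) * sum_{x,y} (U(x,y,t) - mu_U(t))^2 )

with ``mu_U(t)`` the spatial mean over the domain Omega and population
(1/|Omega|) normalization.  Applied to the LL-filtered stack this gives
``sigma_F``, whose local minima mark frozen frames; applied to the
LH-filtered stack it gives ``sigma_G``, which vanishes where no temporal
change occurs.  With psi = d phi / dt the two are tied: every local minimum
of sigma_F corresponds to a (near-)zero of sigma_G.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import SeparableSTFilter, apply_separable, make_temporal_highpass
from .video_io import FrameStack

__all__ = ["EnergySignal", "spatial_std_signal", "energy_pair"]


@dataclass(frozen=True)
class EnergySignal:
    """A sigma_U(t) trace: one non-negative value per frame of the source stack."""

    values: np.ndarray
    role: str = "other"  # {"sigma_F", "sigma_G", "other"}
    t_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("energy signal must be 1-D")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("sigma values must be finite and non-negative")
        t_index = (
            np.arange(1, values.size + 1)
            if self.t_index is None
            else np.asarray(self.t_index, dtype=np.int64)
        )
        if t_index.size != values.size:
            raise ValueError("t_index and values must have equal length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "t_index", t_index)

    def __len__(self) -> int:
        return self.values.size

    @property
    def energy_range(self) -> float:
        """max - min of the trace; the normalizer for the instability threshold."""
        return float(self.values.max() - self.values.min())

    def value_at(self, t: int) -> float:
        """sigma at 1-based frame number ``t`` (in the source stack's numbering)."""
        pos = int(t) - int(self.t_index[0])
        if not (0 <= pos < len(self)):
            raise ValueError(f"frame {t} outside signal range "
                             f"[{self.t_index[0]}, {self.t_index[-1]}]")
        return float(self.values[pos])

    def to_csv(self, path: os.PathLike | str) -> None:
        pd.DataFrame({"frame": self.t_index, "sigma": self.values}).to_csv(
            path, index=False
        )


def spatial_std_signal(stack: FrameStack, role: str = "other") -> EnergySignal:
    """Population spatial standard deviation of every frame of ``stack``."""
    values = stack.frames.std(axis=(1, 2))  # ddof=0: population normalization
    return EnergySignal(values=values, role=role, t_index=stack.t_index)


def energy_pair(
    stack: FrameStack,
    filt_LL: SeparableSTFilter,
    filt_LH: SeparableSTFilter,
) -> tuple[EnergySignal, EnergySignal]:
    """Compute the index-aligned (sigma_F, sigma_G) pair of a stack.

    The two filters must share the spatial kernel and satisfy
    psi = d phi / dt — the hypothesis under which minima of sigma_F mark
    zeros of sigma_G; violating pairs are rejected.
    """
    if filt_LL.mode != "LL" or filt_LH.mode != "LH":
        raise ValueError("energy_pair needs an (LL, LH) filter pair, in that order")
    if filt_LL.rho.shape != filt_LH.rho.shape or not np.allclose(
        filt_LL.rho, filt_LH.rho, atol=1e-12
    ):
        raise ValueError("the LL and LH filters must share the spatial kernel rho")
    expected_psi = make_temporal_highpass(filt_LL.phi)
    if filt_LH.psi.shape != expected_psi.shape or not np.allclose(
        filt_LH.psi, expected_psi, atol=1e-12
    ):
        raise ValueError("psi must be the derivative of phi (psi = d phi / dt)")

    sigma_f = spatial_std_signal(apply_separable(stack, filt_LL), role="sigma_F")
    sigma_g = spatial_std_signal(apply_separable(stack, filt_LH), role="sigma_G")
    return sigma_f, sigma_g
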