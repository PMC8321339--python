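"""Local-minima analysis of the sigma_F energy trace.

Frozen frames appear as local minima of sigma_F(t).  Numerical
instabilities create clusters of shallow minima with nearly equal values;
maximal chains of consecutive minima closer than ``d`` frames whose sigma
values differ by at most ``tau`` times the trace's energy range are
collapsed to their midpoint.  The ``K`` surviving minima with the smallest
sigma values are then selected for group-of-frames extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .energy import EnergySignal

__all__ = [
    "MinimaParams",
    "MinimaResult",
    "find_local_minima",
    "merge_instabilities",
    "select_top_k",
]

DEFAULT_TAU = 0.1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MinimaParams:
    """Instability-removal and selection parameters.

    ``d``: maximum frame distance for two minima to count as adjacent
    (default N/4 for the dataset's maximal expected event length N);
    ``tau``: maximum sigma difference as a fraction of the energy range;
    ``K``: number of minima kept after sorting by sigma value.
    """

    d: int
    tau: float = DEFAULT_TAU
    K: int = 3

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not (0 < self.tau < 1):
            raise ValueError("tau must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class MinimaResult:
    """Raw minima, the instability-merged list, and the top-K selection.

    Each entry is a ``(t, sigma)`` pair with ``t`` a 1-based frame number
    in the source stack's numbering.  ``selected`` is ordered by ascending
    sigma value; ``raw`` and ``merged`` by frame number.
    """

    raw: list[tuple[int, float]]
    merged: list[tuple[int, float]]
    selected: list[tuple[int, float]]

    @property
    def selected_frames(self) -> list[int]:
        return [t for t, _ in self.selected]


def find_local_minima(sig: EnergySignal) -> list[tuple[int, float]]:
    """Interior local minima of an energy trace, as (frame, sigma) pairs.

    A run of equal values bounded on both sides by strictly larger values is
    a single minimum reported at the run's first frame (plateau-head
    convention), so an exactly frozen plateau yields one representative.
    Endpoints are never reported.
    """
    v = sig.values
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 samples to define interior minima")
    out: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i] < v[i - 1] and v[i] < v[j + 1]:
            out.append((int(sig.t_index[i]), float(v[i])))
        i = j + 1
    return out


def _merge_once(
    minima: list[tuple[int, float]], sig: EnergySignal, params: MinimaParams
) -> list[tuple[int, float]]:
    if not minima:
        return []
    threshold = params.tau * sig.energy_range
    merged: list[tuple[int, float]] = []
    run = [minima[0]]
    for cur in minima[1:]:
        prev = run[-1]
        if abs(cur[0] - prev[0]) <= params.d and abs(cur[1] - prev[1]) <= threshold:
            run.append(cur)
        else:
            merged.append(_collapse(run, sig))
            run = [cur]
    merged.append(_collapse(run, sig))
    return merged


def _collapse(run: list[tuple[int, float]], sig: EnergySignal) -> tuple[int, float]:
    if len(run) == 1:
        return run[0]
    t_hat = _round_half_up((run[0][0] + run[-1][0]) / 2.0)
    return t_hat, sig.value_at(t_hat)


def merge_instabilities(
    minima: list[tuple[int, float]],
    sig: EnergySignal,
    params: MinimaParams,
) -> MinimaResult:
    """Collapse chains of unstable minima to their midpoints.

    A maximal chain of consecutive minima, each within ``d`` frames and
    ``tau * energy_range`` in sigma of its predecessor, is replaced by the
    rounded midpoint of the chain, taking sigma at that frame from the
    trace.  Merging is repeated until stable, so the operation is
    idempotent and no consecutive pair of the output still satisfies both
    closeness conditions.
    """
    if any(a[0] >= b[0] for a, b in zip(minima, minima[1:])):
        raise ValueError("minima must be sorted by frame number")
    merged = list(minima)
    while True:
        nxt = _merge_once(merged, sig, params)
        if nxt == merged:
            break
        merged = nxt
    return MinimaResult(raw=list(minima), merged=merged, selected=[])


def select_top_k(result: MinimaResult, K: int) -> MinimaResult:
    """Keep the min(K, M) merged minima of smallest sigma, ascending by sigma.

    Ties are broken by the earlier frame number.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    selected = sorted(result.merged, key=lambda m: (m[1], m[0]))[:K]
    return MinimaResult(raw=result.raw, merged=result.merged, selected=selected)
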