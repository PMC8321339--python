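"""Group-of-frames (GOF) selection around detected frozen-frame minima.

The detector cannot tell whether a frozen pose precedes or follows the
event, so a temporal window centered at each selected minimum is handed to
the downstream spotting stage.  Two conventions coexist deliberately:

* *extraction* windows are clipped to the clip bounds and may overlap —
  this is what a spotting algorithm actually receives;
* *bookkeeping* counts ``(half_before + half_after)`` frames per minimum
  with no clipping and no union — the convention under which published
  per-clip retained-frame percentages are computed, kept so reported
  percentages are comparable with them.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["GOFSet", "build_gofs", "reduction_stats", "gof_report"]

#: default window half-widths (frames) by camera class
HALF_WIDTH_STANDARD = 5    # 25 fps
HALF_WIDTH_HIGHSPEED = 16  # 200 fps


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GOFSet:
    """Extraction windows and retained-frame bookkeeping for one clip."""

    windows: list[tuple[int, int]]  # clipped [start, end] per minimum, 1-based
    minima: list[int]
    half_before: int
    half_after: int
    clip_length: int

    @property
    def retained_count(self) -> int:
        """Unclipped, un-unioned frame count: (hb + ha) per minimum."""
        return (self.half_before + self.half_after) * len(self.windows)

    @property
    def retained_percentage(self) -> int:
        """Integer percentage of the clip retained, capped at 100."""
        pct = _round_half_up(100.0 * self.retained_count / self.clip_length)
        return min(pct, 100)

    @property
    def reduction_percentage(self) -> int:
        return 100 - self.retained_percentage


def build_gofs(
    minima: Sequence[int],
    half_before: int = HALF_WIDTH_STANDARD,
    half_after: int = HALF_WIDTH_STANDARD,
    clip_length: int = 0,
) -> GOFSet:
    """Build one window per minimum: [t - half_before, t + half_after - 1].

    Windows are clipped to [1, clip_length] for extraction; bookkeeping
    stays unclipped (see module docstring).  An empty minima list yields an
    empty set with 0% retained.  Minima whose frame numbers fall outside the
    clip (published detections are sometimes reported in the source video's
    numbering rather than the cut's) still count for bookkeeping; their
    extraction windows collapse to the nearest clip edge.
    """
    if clip_length < 1:
        raise ValueError("clip_length must be >= 1")
    if half_before < 0 or half_after < 0 or half_before + half_after < 1:
        raise ValueError("window half-widths must be non-negative and non-empty")
    windows = [
        (
            min(max(1, t - half_before), clip_length),
            max(min(clip_length, t + half_after - 1), 1),
        )
        for t in minima
    ]
    return GOFSet(
        windows=windows,
        minima=list(minima),
        half_before=half_before,
        half_after=half_after,
        clip_length=clip_length,
    )


def reduction_stats(gofsets: Sequence[GOFSet]) -> tuple[int, int, int]:
    """(mean, max, min) frame-reduction percentage over clips, mean rounded."""
    if not gofsets:
        raise ValueError("need at least one GOFSet")
    reductions = [g.reduction_percentage for g in gofsets]
    mean = _round_half_up(sum(reductions) / len(reductions))
    return mean, max(reductions), min(reductions)


def gof_report(
    gofsets: dict[str, GOFSet], path: os.PathLike | str | None = None
) -> pd.DataFrame:
    """Tabulate windows per sequence; optionally written as CSV."""
    rows = []
    for seq_id, g in gofsets.items():
        if not g.windows:
            rows.append((seq_id, None, None, None, g.retained_percentage))
        for t, (a, b) in zip(g.minima, g.windows):
            rows.append((seq_id, t, a, b, g.retained_percentage))
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "minimum_frame",
            "window_start",
            "window_end",
            "retained_percentage",
        ],
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
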