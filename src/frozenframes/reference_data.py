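"""Published reference detections on the MEVIEW micro-expression clips.

Frozen-frame minima reported for 25 MEVIEW video cuts at 25 fps (N = 8),
with the annotated micro-expression interval, the detected sigma_F minima
(ascending frame order), the printed retained-frame percentage and the cut
length.  Used as a regression oracle for the group-of-frames bookkeeping
(10 frames per minimum: 5 before, 5 after) and for the evaluation
arithmetic; reproducing the detections themselves requires the MEVIEW
videos.

Also included: the published K-sweep on the 255 CASME II sequences
(200 fps, N = 64): the number of sequences whose K smallest-sigma minima
contain a correct detection, for K = 1, 2, 3, 5, 8, 10.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "MeviewRow",
    "MEVIEW_ROWS",
    "MEVIEW_GOF_HALF_WIDTH",
    "CASME2_TOTAL_SEQUENCES",
    "CASME2_KSWEEP_COUNTS",
]


class MeviewRow(NamedTuple):
    sequence_id: str
    onset: int
    offset: int
    minima: tuple[int, ...]  # detected minima, ascending frame order
    printed_percentage: int  # retained-frame percentage as published
    clip_length: int


MEVIEW_GOF_HALF_WIDTH = 5  # 10-frame windows: 5 before, 5 after

MEVIEW_ROWS: tuple[MeviewRow, ...] = (
    MeviewRow("1.1", 49, 62, (37, 63, 74), 33, 89),
    MeviewRow("2.1", 92, 100, (32, 60, 106), 25, 120),
    MeviewRow("3.1", 82, 90, (68, 80, 111), 22, 138),
    MeviewRow("5.2", 75, 81, (54, 72, 85), 17, 174),
    MeviewRow("6.1", 15, 26, (12, 30, 51), 50, 60),
    MeviewRow("7.1", 52, 60, (39, 42, 48), 43, 69),
    MeviewRow("7.3", 93, 98, (17, 56, 89), 30, 101),
    MeviewRow("7.5", 54, 70, (31, 34, 50), 39, 77),
    MeviewRow("7.6", 59, 76, (47, 56, 83), 22, 136),
    MeviewRow("7.8", 81, 90, (53, 59, 80), 27, 112),
    MeviewRow("7.9", 76, 87, (45, 88, 90), 30, 100),
    MeviewRow("8.2", 19, 34, (18, 33, 42), 27, 109),
    MeviewRow("9.1", 88, 96, (76, 83, 88), 55, 55),
    MeviewRow("10.1", 13, 27, (10, 52, 62), 73, 41),
    MeviewRow("10.2", 81, 93, (10, 62, 80), 16, 192),
    MeviewRow("11.2", 7, 21, (11, 29, 35), 79, 38),
    MeviewRow("11.3", 57, 67, (32, 50), 27, 73),
    MeviewRow("11.4", 9, 23, (21, 27, 33), 48, 63),
    MeviewRow("11.5", 33, 49, (20, 38, 50), 48, 63),
    MeviewRow("13.1", 16, 32, (15, 38, 50), 47, 64),
    MeviewRow("13.2", 6, 20, (23, 29, 34), 52, 58),
    MeviewRow("14.1", 35, 41, (42,), 16, 64),
    MeviewRow("14.3", 21, 26, (13, 22, 27), 81, 37),
    MeviewRow("15.1", 36, 41, (30, 42, 55), 47, 64),
    MeviewRow("16.2", 45, 52, (30, 46, 54), 48, 62),
)

CASME2_TOTAL_SEQUENCES = 255
#: correct-detection counts at K = 1, 2, 3, 5, 8, 10
CASME2_KSWEEP_COUNTS: dict[int, int] = {1: 79, 2: 127, 3: 169, 5: 210, 8: 226, 10: 228}
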