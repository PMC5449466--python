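"""Small bundled example datasets.

``COTYLEDON_F2_SEED_COUNTS``: yellow/green seed counts observed in 11
F2 populations of a yellow-cotyledon x green-cotyledon soybean cross, a
classic 15:1 duplicate-dominant segregation example used throughout the
test suite and documentation.

``COTYLEDON_F23_CLASS_COUNTS``: counts of F2:3 family segregation
classes (all-yellow, 3:1, 15:1, all-green) observed in an F2 population
of 495 lines from the same cross, matching the 7:4:4:1 two-gene
expectation.
"""

from __future__ import annotations

from .segregation import SegCounts

__all__ = ["COTYLEDON_F2_SEED_COUNTS", "COTYLEDON_F23_CLASS_COUNTS"]

COTYLEDON_F2_SEED_COUNTS: tuple[SegCounts, ...] = (
    SegCounts(295, 19, line_id="130028-1"),
    SegCounts(319, 22, line_id="130028-3"),
    SegCounts(234, 13, line_id="130028-4"),
    SegCounts(251, 19, line_id="130029-1"),
    SegCounts(232, 20, line_id="130029-2"),
    SegCounts(234, 14, line_id="130030-1"),
    SegCounts(347, 27, line_id="130030-2"),
    SegCounts(231, 16, line_id="130030-3"),
    SegCounts(244, 14, line_id="130030-4"),
    SegCounts(316, 21, line_id="130034-1"),
    SegCounts(277, 25, line_id="130034-2"),
)

# (all_dominant, seg_3_1, seg_15_1, all_recessive)
COTYLEDON_F23_CLASS_COUNTS: tuple[int, int, int, int] = (228, 133, 102, 32)
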