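"""Reference operating parameters and validation counts.

The published validation study behind this tool scored 16 confocal z-stacks
of 3-D cortical cultures, divided into four complexity levels (Level 1:
spherical somata, low neurite outgrowth, low clustering ... Level 4:
complex somata, high outgrowth, medium clustering), against manual counts by
experienced technicians.  Per sample it recorded the actual cell number and
the false-positive / false-negative counts at three stages of the routine:
before automated 3-D error correction, after it, and after correction of
software-flagged probable errors only.

These per-sample counts are bundled so the summary statistics (mean and
n-1 standard deviation of the per-sample error percentages) can be
recomputed, and the per-level operating parameters are exposed as presets.
"""

from __future__ import annotations

from .segment2d import SegmentationParams

__all__ = ["LEVEL_PARAMS", "REFERENCE_COUNTS", "STAGES"]

#: Operating parameters used per complexity level in the validation study:
#: alpha (px), beta, T (%).  The chessboard transform was preferred for the
#: heavily arborized levels 3-4.
LEVEL_PARAMS = {
    1: SegmentationParams(threshold_pct=95.0, alpha=60.0, beta=0.70, transform="euclidean"),
    2: SegmentationParams(threshold_pct=95.0, alpha=40.0, beta=0.70, transform="euclidean"),
    3: SegmentationParams(threshold_pct=95.0, alpha=30.0, beta=0.70, transform="chebyshev"),
    4: SegmentationParams(threshold_pct=95.0, alpha=15.0, beta=0.35, transform="chebyshev"),
}

STAGES = ("before", "after_auto", "after_assisted")

#: Per-sample validation counts, keyed by level then stage; each entry is
#: (actual_cells, false_positives, false_negatives).
REFERENCE_COUNTS = {
    1: {
        "before": [(26, 2, 1), (29, 0, 0), (28, 0, 2), (37, 3, 1)],
        "after_auto": [(26, 0, 1), (29, 0, 0), (28, 0, 2), (37, 1, 1)],
        "after_assisted": [(26, 0, 1), (29, 0, 0), (28, 0, 2), (37, 0, 1)],
    },
    2: {
        "before": [(42, 0, 0), (66, 2, 0), (65, 6, 0), (52, 4, 1), (135, 9, 0)],
        "after_auto": [(42, 0, 0), (66, 2, 0), (65, 3, 0), (52, 1, 1), (135, 5, 0)],
        "after_assisted": [(42, 0, 0), (66, 0, 0), (65, 0, 0), (52, 0, 1), (135, 2, 0)],
    },
    3: {
        "before": [(36, 3, 0), (54, 0, 4), (86, 10, 0), (87, 2, 3)],
        "after_auto": [(36, 1, 0), (54, 0, 4), (86, 10, 0), (87, 1, 3)],
        "after_assisted": [(36, 1, 0), (54, 0, 3), (86, 2, 0), (87, 1, 2)],
    },
    4: {
        "before": [(36, 5, 2), (27, 3, 2), (48, 3, 2)],
        "after_auto": [(36, 1, 2), (27, 2, 2), (48, 0, 2)],
        "after_assisted": [(36, 0, 2), (27, 0, 2), (48, 0, 1)],
    },
}
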