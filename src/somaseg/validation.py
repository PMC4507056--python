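"""Accuracy and error metrics against ground truth.

The conservative scoring used throughout: the *total error percentage* is
``100 * (false positives + false negatives) / actual cells`` — counting both
error types rather than raw count deviation, since spurious and missed cells
can otherwise cancel.  Accuracy is ``100 - total error %``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .merge3d import Cell3D

__all__ = [
    "EvalReport",
    "match_cells",
    "match_label_volumes",
    "summarize_level",
    "parameter_sweep",
]


@dataclass(frozen=True)
class EvalReport:
    """Counts and error percentages of one segmented stack versus truth."""

    actual: int
    predicted: int
    false_pos: int
    false_neg: int

    def __post_init__(self) -> None:
        if min(self.actual, self.predicted, self.false_pos, self.false_neg) < 0:
            raise ValueError("counts must be non-negative")
        if self.predicted != self.actual + self.false_pos - self.false_neg:
            raise ValueError("predicted must equal actual + FP - FN")

    @classmethod
    def from_counts(cls, actual: int, false_pos: int, false_neg: int) -> "EvalReport":
        return cls(actual=actual, predicted=actual + false_pos - false_neg,
                   false_pos=false_pos, false_neg=false_neg)

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.false_pos / self.actual

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.false_neg / self.actual

    @property
    def total_error_pct(self) -> float:
        return 100.0 * (self.false_pos + self.false_neg) / self.actual

    @property
    def accuracy_pct(self) -> float:
        return 100.0 - self.total_error_pct


def _overlap_table(predicted: Sequence[Cell3D], truth: np.ndarray) -> Dict[Tuple[int, int], int]:
    """Shared-voxel counts for every (predicted cell, truth label) pair."""
    table: Dict[Tuple[int, int], int] = {}
    for cell in predicted:
        for m in cell.members:
            z = m.frame_index
            for (r, c) in m.pixels:
                t = int(truth[z, r, c])
                if t > 0:
                    key = (cell.cell_id, t)
                    table[key] = table.get(key, 0) + 1
    return table


def match_cells(predicted: Sequence[Cell3D], truth: np.ndarray) -> EvalReport:
    """Score predicted 3-D cells against a ground-truth label volume.

    Greedy one-to-one assignment in descending order of shared 3-D voxels
    (ties toward lower predicted then truth id); any positive overlap makes
    a pair matchable.  Unmatched predicted cells are false positives,
    unmatched truth cells false negatives.
    """
    truth = np.asarray(truth)
    if truth.ndim != 3:
        raise ValueError("truth must be a (z, h, w) label volume")
    nz, nh, nw = truth.shape
    for cell in predicted:
        for m in cell.members:
            if m.frame_index >= nz or any(r >= nh or c >= nw for (r, c) in m.pixels):
                raise ValueError("predicted cell outside truth volume dimensions")
    truth_ids = {int(t) for t in np.unique(truth) if t > 0}
    table = _overlap_table(predicted, truth)
    pairs = sorted(table.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_pred: set = set()
    used_truth: set = set()
    for (pid, tid), _ in pairs:
        if pid in used_pred or tid in used_truth:
            continue
        used_pred.add(pid)
        used_truth.add(tid)
    fp = len(predicted) - len(used_pred)
    fn = len(truth_ids) - len(used_truth)
    return EvalReport(actual=len(truth_ids), predicted=len(predicted),
                      false_pos=fp, false_neg=fn)


def match_label_volumes(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Score two label volumes (each positive label = one cell)."""
    from .synthgen import volume_to_objects
    from .merge3d import Cell3D as _C

    pred = np.asarray(pred)
    if pred.shape != np.asarray(truth).shape:
        raise ValueError("volume dimensions differ")
    cells = []
    per_cell = volume_to_objects(pred, group_by_cell=True)
    for cid, members in sorted(per_cell.items()):
        cells.append(_C(cell_id=cid, members=sorted(members, key=lambda m: m.frame_index)))
    return match_cells(cells, truth)


def summarize_level(reports: Sequence[EvalReport]) -> Tuple[float, float, float, float]:
    """Level summary: ``(mean_fp_pct, sd_fp_pct, mean_fn_pct, sd_fn_pct)``.

    Per-sample percentages are averaged (not pooled counts); the standard
    deviation uses the n-1 denominator and is 0.0 for a single report.
    Values are rounded to one decimal, the precision at which such summaries
    are conventionally reported.
    """
    if not reports:
        raise ValueError("at least one report required")
    fp = np.array([r.fp_pct for r in reports])
    fn = np.array([r.fn_pct for r in reports])
    sd_fp = float(np.std(fp, ddof=1)) if len(reports) > 1 else 0.0
    sd_fn = float(np.std(fn, ddof=1)) if len(reports) > 1 else 0.0
    return (
        round(float(fp.mean()), 1),
        round(sd_fp, 1),
        round(float(fn.mean()), 1),
        round(sd_fn, 1),
    )


def parameter_sweep(stack, truth: np.ndarray, alphas: Sequence[float],
                    thresholds: Sequence[float], with_3d: bool = True,
                    transform: str = "euclidean", beta: float = 0.70) -> pd.DataFrame:
    """Cell-count error over an (alpha, T) parameter grid.

    Runs the pipeline at every grid point and tabulates the percent count
    deviation ``100*|predicted - actual|/actual``.  With ``with_3d`` the
    full mutual-overlap merge with error correction is used; without it,
    counts come from naive forward-only stitching (singletons kept), the
    pre-correction baseline.  Deterministic: identical inputs give an
    identical surface.

    Returns a DataFrame with columns ``alpha, threshold_pct, predicted,
    count_error_pct``.
    """
    from .segment2d import SegmentationParams, segment_frame
    from .merge3d import merge_stack, stitch_forward_naive

    truth = np.asarray(truth)
    actual = len({int(t) for t in np.unique(truth) if t > 0})
    rows = []
    for t_pct in thresholds:
        for alpha in alphas:
            params = SegmentationParams(threshold_pct=float(t_pct), alpha=float(alpha),
                                        beta=beta, transform=transform)
            frames = []
            for z in range(stack.n_frames):
                _, cands, _ = segment_frame(stack.frames[z], params, stack.bit_depth, z)
                frames.append(cands)
            if with_3d:
                cells, _ = merge_stack(frames, beta)
            else:
                cells = stitch_forward_naive(frames)
            predicted = len(cells)
            rows.append(
                {
                    "alpha": float(alpha),
                    "threshold_pct": float(t_pct),
                    "predicted": predicted,
                    "count_error_pct": 100.0 * abs(predicted - actual) / actual,
                }
            )
    return pd.DataFrame(rows)
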