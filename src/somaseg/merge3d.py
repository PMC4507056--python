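"""Stitch per-frame soma candidates into 3-D cells.

Adjacent-frame objects are linked by *mutual* overlap: an object extends a
growing cell only when it and its best forward candidate are each the
other's best overlap partner among the beta-qualified objects ("unrequited
overlap" — A's best partner preferring a third object — breaks the chain).
Merging runs two projections per step:

Overlap is always judged from two vantage points: a pair qualifies when the
shared pixel count reaches a fraction ``beta`` of *either* object's area.
This lets a small terminal cross-section attach to the larger slice beneath
it, while two fragments lying fully under one larger object both qualify —
which is exactly the conflict signal:

* **forward** — the current object is projected onto the next frame; if
  several next-frame objects qualify, a 2-D over-segmentation is likely:
  the candidates are merged into one composite object and all participants
  are flagged ``forward_multi``.
* **reverse** — the chosen candidate is projected back onto the current
  frame; if several current-frame objects qualify against it, an
  under-segmentation is likely.  Nothing is merged automatically (splitting
  is out of scope); the offenders are flagged ``reverse_multi`` for
  review.

Objects that attach to nothing in either adjacent frame are assumed to be
artifacts or neurite fragments and are dropped: every surviving 3-D cell
spans at least two consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .segment2d import Object2D

__all__ = [
    "FORWARD_MULTI",
    "REVERSE_MULTI",
    "FlagRecord",
    "Cell3D",
    "MergeState",
    "overlap_fraction",
    "forward_candidates",
    "reverse_check",
    "merge_objects_2d",
    "beta_qualified",
    "merge_stack",
    "count_cells",
    "stitch_forward_naive",
]

FORWARD_MULTI = "forward_multi"
REVERSE_MULTI = "reverse_multi"


@dataclass(frozen=True)
class FlagRecord:
    """One object flagged for user review."""

    frame_index: int
    object_id: int
    reason: str  # forward_multi | reverse_multi


@dataclass
class Cell3D:
    """A stitched chain of 2-D objects across consecutive frames."""

    cell_id: int
    members: List[Object2D]
    flagged: bool = False
    flag_reasons: List[str] = field(default_factory=list)

    @property
    def z_start(self) -> int:
        return self.members[0].frame_index

    @property
    def z_end(self) -> int:
        return self.members[-1].frame_index

    @property
    def n_slices(self) -> int:
        return len(self.members)

    @property
    def total_pixels(self) -> int:
        return sum(m.area for m in self.members)

    def voxels(self) -> Set[Tuple[int, int, int]]:
        """All ``(z, row, col)`` voxels of the cell."""
        out: Set[Tuple[int, int, int]] = set()
        for m in self.members:
            out.update((m.frame_index, r, c) for (r, c) in m.pixels)
        return out


@dataclass
class MergeState:
    """Bookkeeping of one merge run.

    ``frames`` holds the final per-frame object tables (forward-merge
    composites replace their parts); ``eligible`` the ids never consumed by
    a chain; ``flags`` every flag raised; ``removed`` the singleton objects
    dropped as artifacts/neurites.
    """

    frames: List[Dict[int, Object2D]]
    eligible: List[Set[int]]
    flags: List[FlagRecord] = field(default_factory=list)
    removed: List[Object2D] = field(default_factory=list)

    def flagged_ids(self, frame_index: int) -> Set[int]:
        return {f.object_id for f in self.flags if f.frame_index == frame_index}


def overlap_fraction(a: Object2D, b: Object2D) -> float:
    """Fraction of ``a``'s pixels shared with ``b`` (``|a ∩ b| / |a|``).

    Pixel coincidence is taken in (row, col) across frames; the measure is
    asymmetric in its arguments.
    """
    if not a.pixels or not b.pixels:
        raise ValueError("overlap_fraction requires non-empty objects")
    return len(a.pixels & b.pixels) / len(a.pixels)


def beta_qualified(a: Object2D, b: Object2D, beta: float) -> bool:
    """Merge qualification: the shared pixels reach ``beta`` of either
    object's area (both vantage points are checked)."""
    shared = len(a.pixels & b.pixels)
    if shared == 0:
        return beta == 0.0
    return shared >= beta * min(len(a.pixels), len(b.pixels))


def forward_candidates(obj: Object2D, next_frame_objects: Iterable[Object2D], beta: float) -> Set[int]:
    """Ids of beta-qualified merge candidates in the next frame.

    Pure candidate lookup; the 2-D merging of multiple candidates (and the
    ``forward_multi`` flagging) is performed by :func:`merge_stack`.
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    return {o.id for o in next_frame_objects if beta_qualified(obj, o, beta)}


def reverse_check(candidate: Object2D, prev_frame_objects: Iterable[Object2D], beta: float) -> Set[int]:
    """Ids of previous-frame objects beta-qualified against the candidate
    (the back projection)."""
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    return {o.id for o in prev_frame_objects if beta_qualified(candidate, o, beta)}


def merge_objects_2d(objects: Sequence[Object2D], new_id: int) -> Object2D:
    """Union several same-frame objects into one composite object."""
    if not objects:
        raise ValueError("nothing to merge")
    frame = objects[0].frame_index
    if any(o.frame_index != frame for o in objects):
        raise ValueError("2-D merge requires objects of one frame")
    pixels = frozenset().union(*(o.pixels for o in objects))
    rows = [r for (r, _) in pixels]
    cols = [c for (_, c) in pixels]
    from .segment2d import _boundary_pixels  # local import to avoid cycle at module load

    return Object2D(
        id=new_id,
        frame_index=frame,
        pixels=pixels,
        centroid=(sum(rows) / len(rows), sum(cols) / len(cols)),
        boundary=_boundary_pixels(pixels),
        cls=objects[0].cls,
    )


def _best_partner(obj: Object2D, pool: Iterable[Object2D], beta: float = 0.0) -> Optional[Object2D]:
    """Greatest-overlap partner of ``obj`` (most shared pixels, ties to the
    smaller id) among those with positive overlap that pass the beta
    qualification; None if no partner qualifies."""
    best = None
    best_key = None
    for o in pool:
        shared = len(obj.pixels & o.pixels)
        if shared > 0 and (beta == 0.0 or beta_qualified(obj, o, beta)):
            key = (-shared, o.id)
            if best_key is None or key < best_key:
                best, best_key = o, key
    return best


def merge_stack(frames: Sequence[Iterable[Object2D]], beta: float):
    """Merge per-frame soma candidates into 3-D cells.

    Frames are processed in ascending z.  Each still-eligible object starts
    a chain that repeatedly (1) collects forward candidates — merging and
    flagging when there are several, (2) back-projects the chosen candidate
    for the under-segmentation check, and (3) extends the chain only on
    mutual best overlap, consuming the candidate's eligibility.  Chains
    shorter than two frames are discarded as artifacts.

    Returns ``(cells, state)`` where ``cells`` is a list of :class:`Cell3D`
    (ids 1..n in creation order) and ``state`` a :class:`MergeState`.
    Deterministic: objects are visited in ascending id order and all ties
    break toward smaller ids.
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    tables: List[Dict[int, Object2D]] = [{o.id: o for o in frame} for frame in frames]
    eligible: List[Set[int]] = [set(t) for t in tables]
    next_id = [max(t, default=0) + 1 for t in tables]
    state = MergeState(frames=tables, eligible=eligible)
    cells: List[Cell3D] = []
    consumed: List[Set[int]] = [set() for _ in tables]

    def flag(frame_index: int, object_id: int, reason: str) -> None:
        rec = FlagRecord(frame_index, object_id, reason)
        if rec not in state.flags:
            state.flags.append(rec)

    for i in range(len(tables)):
        for j in sorted(tables[i]):
            if j not in eligible[i]:
                continue
            eligible[i].discard(j)
            consumed[i].add(j)
            chain = [tables[i][j]]
            k = i
            cur = chain[0]
            while k + 1 < len(tables):
                nxt = tables[k + 1]
                cb_ids = forward_candidates(cur, nxt.values(), beta)
                if not cb_ids:
                    break
                if len(cb_ids) > 1:
                    # 2-D over-segmentation in the next frame: merge and flag.
                    # Only still-eligible parts are merged; a candidate already
                    # consumed by another chain is flagged but left intact so
                    # no pixel ends up in two cells.
                    for c in sorted(cb_ids):
                        flag(k + 1, c, FORWARD_MULTI)
                    flag(k, cur.id, FORWARD_MULTI)
                    mergeable = sorted(c for c in cb_ids if c in eligible[k + 1])
                    if len(mergeable) >= 2:
                        comp = merge_objects_2d([nxt[c] for c in mergeable], next_id[k + 1])
                        next_id[k + 1] += 1
                        for c in mergeable:
                            del nxt[c]
                            eligible[k + 1].discard(c)
                        flag(k + 1, comp.id, FORWARD_MULTI)
                        nxt[comp.id] = comp
                        eligible[k + 1].add(comp.id)
                        b = comp
                    elif mergeable:
                        b = nxt[mergeable[0]]
                    else:
                        break
                else:
                    b = nxt[next(iter(cb_ids))]
                cr_ids = reverse_check(b, tables[k].values(), beta)
                if len(cr_ids) > 1:
                    for c in sorted(cr_ids):
                        flag(k, c, REVERSE_MULTI)
                # mutual best-overlap test: the chain extends only when the
                # current object and its candidate are each the other's
                # greatest-overlap partner.  beta gates candidacy (forward
                # projection); the mutuality itself is a pure argmax in both
                # directions, so a small terminal cross-section can still
                # attach to the larger slice below it.
                if _best_partner(cur, nxt.values(), beta) is not b:
                    break
                back = _best_partner(b, tables[k].values())
                if back is None or back.id != cur.id:
                    break
                chain.append(b)
                eligible[k + 1].discard(b.id)
                consumed[k + 1].add(b.id)
                k += 1
                cur = b
            if len(chain) >= 2:
                flag_ids = [
                    f.reason
                    for m in chain
                    for f in state.flags
                    if f.frame_index == m.frame_index and f.object_id == m.id
                ]
                cells.append(
                    Cell3D(
                        cell_id=len(cells) + 1,
                        members=chain,
                        flagged=bool(flag_ids),
                        flag_reasons=sorted(set(flag_ids)),
                    )
                )
            else:
                state.removed.append(chain[0])
    return cells, state


def count_cells(cells: Iterable[Cell3D]) -> int:
    """Number of distinct 3-D cells."""
    return len(list(cells))


def stitch_forward_naive(frames: Sequence[Iterable[Object2D]]) -> List[Cell3D]:
    """Forward-only stitching with no error handling — the pre-correction
    baseline.

    Chains follow the single best forward overlap (> 0; no beta test, no
    mutuality, no flags) and singletons are kept as cells.  This is the
    stage whose counts are inflated by one-slice artifacts and
    over-segmented fragments, against which the corrected pipeline is
    compared.
    """
    tables = [{o.id: o for o in frame} for frame in frames]
    eligible = [set(t) for t in tables]
    cells: List[Cell3D] = []
    for i in range(len(tables)):
        for j in sorted(tables[i]):
            if j not in eligible[i]:
                continue
            eligible[i].discard(j)
            chain = [tables[i][j]]
            k = i
            cur = chain[0]
            while k + 1 < len(tables):
                pool = [tables[k + 1][c] for c in sorted(eligible[k + 1])]
                best = _best_partner(cur, pool) if pool else None
                if best is None or not (cur.pixels & best.pixels):
                    break
                chain.append(best)
                eligible[k + 1].discard(best.id)
                k += 1
                cur = best
            cells.append(Cell3D(cell_id=len(cells) + 1, members=chain))
    return cells
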