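"""2-D/3-D cell databases and the programmatic correction API.

The database catalogs every soma-candidate 2-D object per frame together
with the stitched 3-D cells and their geometric statistics (per-slice area,
equivalent diameter ``2*sqrt(area/pi)``, eccentricity from the second
central moments' ellipse, concavity ``1 - area/convex_hull_area``).  The
edit operations are the headless equivalents of the interactive click
commands: add/delete a 2-D cell, merge over-segmented 2-D cells, and draw a
manual boundary.  Every edit re-evaluates the 3-D linkage under the mutual
beta-overlap criterion, so counts and statistics stay consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.measure import label as sk_label, regionprops

from .segment2d import Object2D, SOMA_CANDIDATE
from .merge3d import Cell3D, MergeState, merge_stack

__all__ = [
    "CellDatabase",
    "build_database",
    "add_cell",
    "delete_cell",
    "merge_cells",
    "manual_boundary",
    "candidate_at",
    "equivalent_diameter",
    "object_geometry",
]


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given pixel area: ``2*sqrt(A/pi)``."""
    return 2.0 * math.sqrt(area / math.pi)


def _object_mask(obj: Object2D):
    rows = [r for (r, _) in obj.pixels]
    cols = [c for (_, c) in obj.pixels]
    r0, c0 = min(rows), min(cols)
    mask = np.zeros((max(rows) - r0 + 1, max(cols) - c0 + 1), dtype=bool)
    for (r, c) in obj.pixels:
        mask[r - r0, c - c0] = True
    return mask, (r0, c0)


def object_geometry(obj: Object2D) -> Dict[str, float]:
    """Per-object geometry: area, equivalent diameter, eccentricity,
    concavity (1 - area / convex-hull area)."""
    mask, _ = _object_mask(obj)
    props = regionprops(mask.astype(np.uint8))[0]
    concavity = 1.0 - obj.area / props.area_convex if props.area_convex else 0.0
    return {
        "area": float(obj.area),
        "equiv_diameter": equivalent_diameter(obj.area),
        "eccentricity": float(props.eccentricity),
        "concavity": float(concavity),
    }


def _is_connected(pixels: Iterable[Tuple[int, int]]) -> bool:
    pts = list(pixels)
    if not pts:
        return False
    rows = [r for (r, _) in pts]
    cols = [c for (_, c) in pts]
    r0, c0 = min(rows), min(cols)
    mask = np.zeros((max(rows) - r0 + 1, max(cols) - c0 + 1), dtype=bool)
    for (r, c) in pts:
        mask[r - r0, c - c0] = True
    return sk_label(mask, connectivity=2).max() == 1


@dataclass
class CellDatabase:
    """Catalog of 2-D objects, 3-D cells, and their statistics.

    ``objects2d[z]`` maps object id -> :class:`Object2D` for frame ``z``
    (all soma candidates, stitched or not — these are the "potential cells"
    the assisted-segmentation lookup searches); ``cells`` the current 3-D
    cells; ``beta`` the overlap threshold used whenever linkage is
    re-evaluated; ``shape`` the (z, h, w) volume dimensions.
    """

    objects2d: List[Dict[int, Object2D]]
    cells: List[Cell3D]
    state: MergeState
    beta: float
    shape: Tuple[int, int, int]

    # ------------------------------------------------------------------ stats
    def cell_stats(self, cell_id: int) -> Dict:
        cell = self._cell(cell_id)
        areas = [m.area for m in cell.members]
        vox = np.array(
            [(m.frame_index, r, c) for m in cell.members for (r, c) in m.pixels], dtype=float
        )
        zc, rc, cc = vox.mean(axis=0)
        geoms = [object_geometry(m) for m in cell.members]
        return {
            "total_pixels": cell.total_pixels,
            "slice_areas": areas,
            "equiv_diameters": [equivalent_diameter(a) for a in areas],
            "equiv_diameter_mean": float(np.mean([equivalent_diameter(a) for a in areas])),
            "eccentricity_mean": float(np.mean([g["eccentricity"] for g in geoms])),
            "concavity_mean": float(np.mean([g["concavity"] for g in geoms])),
            # centroid as (x, y, z) = (col, row, frame)
            "centroid": (float(cc), float(rc), float(zc)),
        }

    def count_cells(self) -> int:
        return len(self.cells)

    def _cell(self, cell_id: int) -> Cell3D:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"no cell with id {cell_id}")

    def _next_object_id(self, frame_index: int) -> int:
        return max(self.objects2d[frame_index], default=0) + 1

    # -------------------------------------------------------------- invariants
    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        seen: Set[Tuple[int, int]] = set()
        for cell in self.cells:
            assert cell.n_slices >= 2, "cell spans fewer than 2 frames"
            zs = [m.frame_index for m in cell.members]
            assert zs == list(range(zs[0], zs[-1] + 1)), "cell frames not consecutive"
            for m in cell.members:
                key = (m.frame_index, m.id)
                assert key not in seen, "object appears in two cells"
                seen.add(key)
                assert m.id in self.objects2d[m.frame_index], "cell member missing from 2-D table"
                assert self.objects2d[m.frame_index][m.id].pixels == m.pixels
        # no pixel double-counted across cells
        voxels: Set[Tuple[int, int, int]] = set()
        total = 0
        for cell in self.cells:
            v = cell.voxels()
            total += len(v)
            voxels |= v
        assert total == len(voxels), "voxel claimed by two cells"

    # ------------------------------------------------------------- re-stitching
    def _restitch(self) -> None:
        frames = [list(t.values()) for t in self.objects2d]
        self.cells, self.state = merge_stack(frames, self.beta)
        # forward merges during re-stitching may have produced composites;
        # reflect the final object tables
        self.objects2d = self.state.frames


def build_database(cells: Sequence[Cell3D], frames: Sequence[Iterable[Object2D]],
                   beta: float, shape: Tuple[int, int, int],
                   state: Optional[MergeState] = None) -> CellDatabase:
    """Assemble a database from a merge run.

    ``frames`` are the post-merge per-frame object tables (composites
    included); ``shape`` the (z, h, w) volume dimensions.
    """
    objects2d = [{o.id: o for o in frame} for frame in frames]
    if state is None:
        state = MergeState(frames=objects2d, eligible=[set() for _ in objects2d])
    return CellDatabase(objects2d=objects2d, cells=list(cells), state=state,
                        beta=beta, shape=shape)


def add_cell(db: CellDatabase, frame_index: int, pixels: Iterable[Tuple[int, int]]) -> CellDatabase:
    """Insert a new 2-D object and re-evaluate 3-D linkage.

    ``pixels`` must be a non-empty 8-connected set inside the frame.
    Returns the (mutated) database.
    """
    pts = frozenset((int(r), int(c)) for (r, c) in pixels)
    if not pts:
        raise ValueError("empty pixel set")
    _, h, w = db.shape
    if any(not (0 <= r < h and 0 <= c < w) for (r, c) in pts):
        raise ValueError("pixels outside frame bounds")
    if not _is_connected(pts):
        raise ValueError("pixel set is not connected")
    oid = db._next_object_id(frame_index)
    rows = [r for (r, _) in pts]
    cols = [c for (_, c) in pts]
    from .segment2d import _boundary_pixels

    db.objects2d[frame_index][oid] = Object2D(
        id=oid, frame_index=frame_index, pixels=pts,
        centroid=(sum(rows) / len(rows), sum(cols) / len(cols)),
        boundary=_boundary_pixels(pts), cls=SOMA_CANDIDATE,
    )
    db._restitch()
    return db


def delete_object(db: CellDatabase, frame_index: int, object_id: int) -> CellDatabase:
    """Remove one 2-D object (whether or not it belongs to a cell) and
    re-evaluate 3-D linkage."""
    if object_id not in db.objects2d[frame_index]:
        raise KeyError(f"no object {object_id} in frame {frame_index}")
    del db.objects2d[frame_index][object_id]
    db._restitch()
    return db


def delete_cell(db: CellDatabase, cell_id: int, frame_index: int) -> CellDatabase:
    """Delete a 3-D cell's 2-D member in the given frame.

    Remaining members re-stitch under the beta criterion; a remaining
    singleton is dropped by the artifact rule, so deleting one slice of a
    2-slice cell removes the whole cell.
    """
    cell = db._cell(cell_id)
    member = next((m for m in cell.members if m.frame_index == frame_index), None)
    if member is None:
        raise KeyError(f"cell {cell_id} has no member in frame {frame_index}")
    return delete_object(db, frame_index, member.id)


def merge_cells(db: CellDatabase, cell_id_a: int, cell_id_b: int, frame_index: int) -> CellDatabase:
    """Merge two over-segmented cells' 2-D objects in one frame.

    Both cells must have members in ``frame_index``; the two pixel sets are
    united into one object and the 3-D chains are re-stitched.
    """
    if cell_id_a == cell_id_b:
        raise ValueError("cannot merge a cell with itself")
    ma = next((m for m in db._cell(cell_id_a).members if m.frame_index == frame_index), None)
    mb = next((m for m in db._cell(cell_id_b).members if m.frame_index == frame_index), None)
    if ma is None or mb is None:
        raise ValueError(f"both cells must have members in frame {frame_index}")
    from .merge3d import merge_objects_2d

    comp = merge_objects_2d([ma, mb], db._next_object_id(frame_index))
    del db.objects2d[frame_index][ma.id]
    del db.objects2d[frame_index][mb.id]
    db.objects2d[frame_index][comp.id] = comp
    db._restitch()
    return db


def manual_boundary(db: CellDatabase, frame_index: int, polygon: Sequence[Tuple[float, float]]) -> CellDatabase:
    """Rasterize a hand-drawn boundary into a new 2-D object.

    ``polygon`` is an ordered list of >= 3 ``(row, col)`` vertices forming a
    simple polygon.  A pixel belongs to the object if its center lies inside
    or on the boundary (even-odd rule).  A drawn boundary identical to an
    existing object replaces it.
    """
    if len(polygon) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon([(float(c), float(r)) for (r, c) in polygon])
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon is degenerate or self-intersecting")
    _, h, w = db.shape
    rmin = max(0, int(math.floor(poly.bounds[1])))
    rmax = min(h - 1, int(math.ceil(poly.bounds[3])))
    cmin = max(0, int(math.floor(poly.bounds[0])))
    cmax = min(w - 1, int(math.ceil(poly.bounds[2])))
    pts = frozenset(
        (r, c)
        for r in range(rmin, rmax + 1)
        for c in range(cmin, cmax + 1)
        if poly.covers(Point(c, r))
    )
    if not pts:
        raise ValueError("polygon covers no pixel centers")
    # identical to an existing object -> replace it
    for oid, obj in list(db.objects2d[frame_index].items()):
        if obj.pixels == pts:
            del db.objects2d[frame_index][oid]
    return add_cell(db, frame_index, pts)


def candidate_at(db: CellDatabase, frame_index: int, point: Tuple[int, int]) -> Optional[Object2D]:
    """The stored potential 2-D object whose pixels contain ``point``.

    Used by software-assisted manual segmentation: the user's click is
    compared against the per-frame database of potential cells.  Background
    and watershed-line positions return None; out-of-bounds points raise.
    """
    r, c = int(point[0]), int(point[1])
    _, h, w = db.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"point {point} outside frame bounds {(h, w)}")
    for obj in db.objects2d[frame_index].values():
        if (r, c) in obj.pixels:
            return obj
    return None
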