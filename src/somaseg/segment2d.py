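"""Per-frame soma segmentation: thresholding, distance transforms, watershed,
and area-based classification of watershed regions.

The 2-D stage turns one fluorescence frame into a set of labeled regions and
sorts them into soma candidates versus neurite fragments.  Neurites, with
their mottled outlines, fracture into many small watershed regions, while the
smooth, near-saturated somata yield large round regions; a single pixel-area
threshold ``alpha`` separates the two populations.

Conventions used throughout:

* coordinates are 0-based ``(row, col)`` with row = y downward, col = x
  rightward;
* 8-connectivity for region labeling, seed plateaus and flooding;
* the frame border is treated as background, so objects touching the edge
  still receive finite distance values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.morphology import local_maxima
from skimage.segmentation import watershed as sk_watershed

__all__ = [
    "SegmentationParams",
    "DistanceMap",
    "Object2D",
    "SOMA_CANDIDATE",
    "NEURITE_FRAGMENT",
    "global_threshold",
    "erode_diamond",
    "distance_transform",
    "watershed_segment",
    "label_objects",
    "area_histogram",
    "classify_by_area",
    "segment_frame",
]

SOMA_CANDIDATE = "soma_candidate"
NEURITE_FRAGMENT = "neurite_fragment"

#: 3x3 diamond (center + 4-neighbors), the optional erosion kernel.
_DIAMOND = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """User tunables of the segmentation pipeline.

    Parameters
    ----------
    threshold_pct : float
        Global intensity threshold T, as a percent of the maximum
        representable intensity (``(0, 100]``).  A pixel is foreground iff
        ``intensity >= T/100 * (2**bit_depth - 1)``.
    alpha : float
        Pixel-area threshold separating soma candidates (``area >= alpha``)
        from neurite fragments (``area < alpha``).
    beta : float
        Overlap threshold in ``[0, 1]`` used by the 3-D stitching stage.
    transform : str
        ``"euclidean"`` or ``"chebyshev"`` distance metric for the
        watershed-seeding transform.
    erode : bool
        Apply one pass of 3x3 diamond erosion to the binary mask before the
        distance transform (useful for heavily clustered cultures).
    """

    threshold_pct: float = 95.0
    alpha: float = 60.0
    beta: float = 0.70
    transform: str = "euclidean"
    erode: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.threshold_pct <= 100:
            raise ValueError("threshold_pct must lie in (0, 100]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.transform not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class DistanceMap:
    """Distance-to-background map of one binary frame.

    ``values`` is zero exactly on background pixels; each foreground pixel
    holds its minimum metric distance to the nearest background pixel, with
    the frame border padded as background.
    """

    values: np.ndarray
    metric: str


@dataclass(frozen=True)
class Object2D:
    """One watershed region in one frame.

    ``pixels`` is a frozenset of ``(row, col)`` tuples; ``boundary`` is the
    subset of pixels with at least one 8-neighbor (or off-frame position)
    outside the object, ordered lexicographically.
    """

    id: int
    frame_index: int
    pixels: frozenset
    centroid: tuple
    boundary: tuple = ()
    cls: str = SOMA_CANDIDATE

    @property
    def area(self) -> int:
        return len(self.pixels)

    def with_class(self, cls: str) -> "Object2D":
        return replace(self, cls=cls)


def global_threshold(frame: np.ndarray, threshold_pct: float, bit_depth: int) -> np.ndarray:
    """Binarize a frame with a global intensity threshold.

    A pixel maps to foreground iff its intensity is at least
    ``threshold_pct/100 * (2**bit_depth - 1)`` (inclusive comparison).
    Returns a boolean mask of the same shape.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in (0, 100]")
    cutoff = threshold_pct / 100.0 * (2**bit_depth - 1)
    return np.asarray(frame, dtype=float) >= cutoff


def erode_diamond(mask: np.ndarray) -> np.ndarray:
    """Binary erosion with the 5-element diamond; off-frame pixels count as
    background (so a border pixel never survives)."""
    return ndi.binary_erosion(np.asarray(mask, dtype=bool), structure=_DIAMOND, border_value=0)


def distance_transform(mask: np.ndarray, metric: str = "euclidean") -> DistanceMap:
    """Distance of each foreground pixel to the nearest background pixel.

    ``metric`` is ``"euclidean"`` (sqrt((x-xb)^2 + (y-yb)^2)) or
    ``"chebyshev"`` (max(|x-xb|, |y-yb|), the chessboard distance).  The
    frame is padded with a one-pixel background ring before the transform so
    that edge-touching foreground always has a finite distance, then cropped
    back.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    if metric == "euclidean":
        dist = ndi.distance_transform_edt(padded)
    elif metric == "chebyshev":
        dist = ndi.distance_transform_cdt(padded, metric="chessboard").astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMap(values=dist[1:-1, 1:-1], metric=metric)


def watershed_segment(dist: DistanceMap) -> np.ndarray:
    """Watershed the negated distance map, seeded at regional maxima.

    Seeds are the 8-connected regional-maximum plateaus of the distance map
    (the deepest points of the inverted surface); flooding is restricted to
    foreground.  Watershed-line pixels and background receive label 0; each
    positive label is one 8-connected region containing its seed.
    """
    values = dist.values
    mask = values > 0
    if not mask.any():
        return np.zeros(values.shape, dtype=np.int32)
    maxima = local_maxima(values, connectivity=2) & mask
    markers = sk_label(maxima, connectivity=2)
    labels = sk_watershed(-values, markers=markers, mask=mask, connectivity=2, watershed_line=True)
    labels = labels.astype(np.int32)
    # carving out the watershed lines can strand slivers of a basin on the
    # far side of a line; keep only the component attached to the seed so
    # every region stays 8-connected
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        comps = sk_label(labels == lab, connectivity=2)
        if comps.max() > 1:
            keep = set(np.unique(comps[(markers == lab) & (comps > 0)]))
            labels[(comps > 0) & ~np.isin(comps, sorted(keep))] = 0
    return labels


def _boundary_pixels(pixel_set: frozenset) -> tuple:
    out = []
    for (r, c) in pixel_set:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                if (r + dr, c + dc) not in pixel_set:
                    out.append((r, c))
                    break
            else:
                continue
            break
    return tuple(sorted(out))


def label_objects(labels: np.ndarray, frame_index: int) -> list:
    """Turn a label frame into :class:`Object2D` records (ids = label values,
    ascending)."""
    labels = np.asarray(labels)
    objects = []
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        pixels = frozenset(zip(rows.tolist(), cols.tolist()))
        centroid = (float(rows.mean()), float(cols.mean()))
        objects.append(
            Object2D(
                id=int(lab),
                frame_index=frame_index,
                pixels=pixels,
                centroid=centroid,
                boundary=_boundary_pixels(pixels),
            )
        )
    return objects


def area_histogram(objects: Iterable[Object2D], bin_width: float = 10.0):
    """Histogram of object pixel areas, for user selection of ``alpha``.

    Returns ``(bin_edges, counts)`` with bins ``[0, w), [w, 2w), ...``
    covering the largest area.  An empty object set yields empty arrays.
    The distribution is typically bimodal: a sharp mode of small fractured
    neurite fragments and a broad mode of large soma regions.
    """
    areas = np.array([o.area for o in objects], dtype=float)
    if areas.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    n_bins = int(np.floor(areas.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(areas, bins=edges)
    return edges, counts


def classify_by_area(objects: Iterable[Object2D], alpha: float):
    """Split objects into ``(soma_candidates, neurite_fragments)``.

    ``area >= alpha`` makes a soma candidate (inclusive boundary);
    fragments play no further role in 3-D stitching.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    candidates, fragments = [], []
    for obj in objects:
        if obj.area >= alpha:
            candidates.append(obj.with_class(SOMA_CANDIDATE))
        else:
            fragments.append(obj.with_class(NEURITE_FRAGMENT))
    return candidates, fragments


def segment_frame(frame: np.ndarray, params: SegmentationParams, bit_depth: int, frame_index: int = 0):
    """Run the full 2-D stage on one frame.

    threshold -> (optional diamond erosion) -> distance transform ->
    watershed -> object extraction -> area classification.

    Returns ``(labels, soma_candidates, neurite_fragments)``.
    """
    mask = global_threshold(frame, params.threshold_pct, bit_depth)
    if params.erode:
        mask = erode_diamond(mask)
    dist = distance_transform(mask, params.transform)
    labels = watershed_segment(dist)
    objects = label_objects(labels, frame_index)
    candidates, fragments = classify_by_area(objects, params.alpha)
    return labels, candidates, fragments
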