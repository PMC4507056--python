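"""Synthetic fluorescence z-stacks with voxel-level ground truth.

The generator emulates single-channel confocal stacks of 3-D neuronal
cultures at four complexity levels: Level 1 — spherical somata, low neurite
outgrowth, low clustering; Level 2 — spherical, medium outgrowth, low
clustering; Level 3 — spherical, high outgrowth, medium clustering;
Level 4 — complex (deformed) somata, high outgrowth, medium clustering.

Somata are solid spheres (Level 4: random ellipsoids with surface bumps)
rendered at or above saturation, mimicking acquisition tuned for the fine
neurite features; neurites are thin (1-3 px) persistent random-walk tubes,
also near saturation, whose mottled outlines fracture under watershed.
Additive Gaussian noise is applied and clipped to the bit depth.  Ground
truth labels soma voxels only (neurites excluded) and every soma spans at
least two frames.

The axial sampling is coarser than the lateral one, as in real confocal
stacks: ``z_scale`` pixels of depth separate consecutive frames, so a soma
of radius 4-8 px occupies roughly 3-6 slices at the default spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stack_io import IntensityStack
from .segment2d import Object2D, SOMA_CANDIDATE

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlacementError",
    "LEVEL_PRESETS",
    "make_spec",
    "generate_stack",
    "volume_to_objects",
    "truth_objects",
    "corrupt_with_oversegmentation",
]


class PlacementError(RuntimeError):
    """Raised when somata cannot be placed without forced total overlap."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic stack.

    ``volume`` is (frames, height, width); ``soma_radius_range`` in pixels;
    ``clustering`` the fraction of somata placed within 1.5 radii of
    another; ``neurite_count_per_soma``, ``neurite_width`` and
    ``neurite_length_range`` control the arborization; ``noise_sd`` the
    additive Gaussian noise in intensity units; ``z_scale`` the depth (px)
    between consecutive frames.
    """

    level: int = 1
    volume: Tuple[int, int, int] = (16, 256, 256)
    n_somata: int = 20
    # cortical somata are 10-20 μm across; at the 0.9 μm/px scale of a
    # 512-px field spanning ~460 μm that is a radius of roughly 5.5-11 px
    soma_radius_range: Tuple[float, float] = (5.5, 10.0)
    soma_shape: str = "sphere"  # sphere | deformed
    clustering: float = 0.0
    neurite_count_per_soma: Tuple[int, int] = (0, 2)
    neurite_width: Tuple[int, int] = (1, 3)
    neurite_length_range: Tuple[float, float] = (20.0, 60.0)
    noise_sd: float = 5.0
    seed: int = 0
    z_scale: float = 2.5
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValueError("level must be 1-4")
        if self.soma_shape not in ("sphere", "deformed"):
            raise ValueError("soma_shape must be 'sphere' or 'deformed'")
        if self.soma_shape == "deformed" and self.level != 4:
            raise ValueError("deformed somata are a level-4 feature")
        if not 0 <= self.clustering <= 1:
            raise ValueError("clustering must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Voxel-level truth: ``label_volume`` of soma ids (0 background,
    neurites excluded), per-cell centroids (z_px, row, col) and radii."""

    label_volume: np.ndarray
    n_cells: int
    centroids: List[Tuple[float, float, float]]
    radii: List[float]
    z_scale: float


#: Level presets following the four culture-complexity conditions.
LEVEL_PRESETS: Dict[int, Dict] = {
    1: dict(soma_shape="sphere", neurite_count_per_soma=(0, 2), clustering=0.0),
    2: dict(soma_shape="sphere", neurite_count_per_soma=(2, 5), clustering=0.05),
    3: dict(soma_shape="sphere", neurite_count_per_soma=(5, 9), clustering=0.30),
    4: dict(soma_shape="deformed", neurite_count_per_soma=(5, 9), clustering=0.30),
}


def make_spec(level: int, **overrides) -> SyntheticSpec:
    """A :class:`SyntheticSpec` from the level preset, with overrides."""
    kwargs = dict(LEVEL_PRESETS[level])
    kwargs.update(overrides)
    return SyntheticSpec(level=level, **kwargs)


# --------------------------------------------------------------------------
# rendering internals
# --------------------------------------------------------------------------

# pre-clip brightness levels; somata and neurites sit above the saturation
# point so the clipped image reproduces acquisition tuned for fine features
_SOMA_BRIGHTNESS = 270.0
_NEURITE_BRIGHTNESS = 260.0
_BACKGROUND = 8.0


def _place_somata(spec: SyntheticSpec, rng: np.random.Generator):
    nz, nh, nw = spec.volume
    depth = (nz - 1) * spec.z_scale
    r_lo, r_hi = spec.soma_radius_range
    radii = rng.uniform(r_lo, r_hi, size=spec.n_somata)
    if 2 * radii.max() > depth or 2 * radii.max() > min(nh, nw) - 4:
        raise PlacementError("volume too small for the requested soma radii")
    n_clustered = int(round(spec.clustering * spec.n_somata))
    centers: List[Tuple[float, float, float]] = []

    def ok(pos, r, ignore=None) -> bool:
        for idx, (p, pr) in enumerate(zip(centers, radii)):
            if idx == ignore:
                continue
            d = math.dist(pos, p)
            if d < r + pr + 2.0:
                return False
        return True

    for i in range(spec.n_somata):
        r = radii[i]
        placed = False
        for _ in range(4000):
            if i >= spec.n_somata - n_clustered and centers:
                a = int(rng.integers(len(centers)))
                anchor, ra = centers[a], radii[a]
                # contact distance: somata are solid bodies, so clustered
                # cells touch or indent slightly rather than interpenetrate
                d = rng.uniform(0.85, 1.1) * (r + ra)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos = (
                    float(np.clip(anchor[0] + d * u[0], r, depth - r)),
                    float(np.clip(anchor[1] + d * u[1], r + 2, nh - r - 3)),
                    float(np.clip(anchor[2] + d * u[2], r + 2, nw - r - 3)),
                )
                if ok(pos, r, ignore=a):
                    centers.append(pos)
                    placed = True
                    break
            else:
                pos = (
                    float(rng.uniform(r, depth - r)),
                    float(rng.uniform(r + 2, nh - r - 3)),
                    float(rng.uniform(r + 2, nw - r - 3)),
                )
                if ok(pos, r):
                    centers.append(pos)
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place soma {i + 1}/{spec.n_somata} after bounded retries"
            )
    return centers, radii


def _soma_cross_sections(spec: SyntheticSpec, center, radius, axes, bumps):
    """Yield (frame_index, boolean cross-section mask, squared-distance map)."""
    nz, nh, nw = spec.volume
    zc, rc, cc = center
    rr, cols = np.mgrid[0:nh, 0:nw]
    for z in range(nz):
        dz = z * spec.z_scale - zc
        if abs(dz) > 1.6 * radius:
            continue
        if axes is None:
            if abs(dz) >= radius:
                inside = np.zeros((nh, nw), dtype=bool)
            else:
                r2d = math.sqrt(radius**2 - dz**2)
                inside = (rr - rc) ** 2 + (cols - cc) ** 2 <= r2d**2
        else:
            az, ar, ac = axes
            q = (dz / az) ** 2 + ((rr - rc) / ar) ** 2 + ((cols - cc) / ac) ** 2
            inside = q <= 1.0
        for (bz, br, bc, brad) in bumps:
            dbz = z * spec.z_scale - bz
            if abs(dbz) < brad:
                rb = math.sqrt(brad**2 - dbz**2)
                inside |= (rr - br) ** 2 + (cols - bc) ** 2 <= rb**2
        if inside.any():
            d2 = (z * spec.z_scale - zc) ** 2 + (rr - rc) ** 2 + (cols - cc) ** 2
            yield z, inside, d2


def _render_neurites(spec: SyntheticSpec, rng: np.random.Generator,
                     intensity: np.ndarray, centers, radii) -> None:
    nz, nh, nw = spec.volume
    depth = (nz - 1) * spec.z_scale
    lo, hi = spec.neurite_count_per_soma
    for (center, radius) in zip(centers, radii):
        n_neur = int(rng.integers(lo, hi + 1))
        for _ in range(n_neur):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = np.array(center) + u * (radius + 0.5)
            length = rng.uniform(*spec.neurite_length_range)
            width = int(rng.integers(spec.neurite_width[0], spec.neurite_width[1] + 1))
            half = max(0.5, width / 2.0)
            n_steps = int(length)
            for _ in range(n_steps):
                # persistent random walk: direction decorrelates slowly
                u = 0.85 * u + 0.35 * rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos = pos + u
                if not (0 <= pos[0] <= depth and 1 <= pos[1] < nh - 1 and 1 <= pos[2] < nw - 1):
                    break
                z = int(round(pos[0] / spec.z_scale))
                if not 0 <= z < nz:
                    break
                r0, c0 = int(round(pos[1])), int(round(pos[2]))
                # mottled outline: the tube radius varies spot to spot, so the
                # rendered neurite is spiny and dimpled and fractures into
                # many small regions under watershed instead of forming one
                # smooth tube
                half_t = half * rng.uniform(0.35, 1.15)
                w = int(math.ceil(half_t))
                for dr in range(-w, w + 1):
                    for dc in range(-w, w + 1):
                        if dr * dr + dc * dc <= half_t * half_t + 1e-9:
                            r, c = r0 + dr, c0 + dc
                            if 0 <= r < nh and 0 <= c < nw:
                                intensity[z, r, c] = max(intensity[z, r, c], _NEURITE_BRIGHTNESS)


def generate_stack(spec: SyntheticSpec):
    """Render a synthetic stack; returns ``(IntensityStack, GroundTruth)``.

    Deterministic given ``spec.seed``.  Raises :class:`PlacementError` when
    the volume cannot host ``n_somata`` without forced total overlap.
    """
    rng = np.random.default_rng(spec.seed)
    nz, nh, nw = spec.volume
    centers, radii = _place_somata(spec, rng)

    intensity = np.full(spec.volume, _BACKGROUND, dtype=np.float64)
    labels = np.zeros(spec.volume, dtype=np.uint16)
    best_d2 = np.full(spec.volume, np.inf)

    for i, (center, radius) in enumerate(zip(centers, radii), start=1):
        if spec.soma_shape == "deformed":
            axes = tuple(radius * rng.uniform(0.7, 1.3, size=3))
            n_bumps = int(rng.integers(1, 4))
            bumps = []
            for _ in range(n_bumps):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                bpos = np.array(center) + u * radius * 0.9
                bumps.append((bpos[0], bpos[1], bpos[2], radius * rng.uniform(0.25, 0.45)))
        else:
            axes = None
            bumps = []
        for z, inside, d2 in _soma_cross_sections(spec, center, radius, axes, bumps):
            intensity[z][inside] = _SOMA_BRIGHTNESS
            claim = inside & (d2 < best_d2[z])
            labels[z][claim] = i
            best_d2[z][claim] = d2[claim]

    _render_neurites(spec, rng, intensity, centers, radii)

    noisy = intensity + rng.normal(0.0, spec.noise_sd, size=spec.volume)
    max_val = 2**spec.bit_depth - 1
    frames = np.clip(noisy, 0, max_val)
    frames = frames.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    kept = [int(v) for v in np.unique(labels) if v > 0]
    spans = {v: len({z for z in range(nz) if (labels[z] == v).any()}) for v in kept}
    thin = [v for v in kept if spans[v] < 2]
    if thin:  # a soma fully hidden between planes cannot be a valid truth cell
        raise PlacementError(f"somata {thin} span fewer than 2 frames; adjust z_scale or radii")

    truth = GroundTruth(
        label_volume=labels,
        n_cells=len(kept),
        centroids=[tuple(c) for c in centers],
        radii=[float(r) for r in radii],
        z_scale=spec.z_scale,
    )
    stack = IntensityStack(frames=frames, bit_depth=spec.bit_depth)
    return stack, truth


# --------------------------------------------------------------------------
# truth -> 2-D object fixtures
# --------------------------------------------------------------------------

def volume_to_objects(volume: np.ndarray, group_by_cell: bool = False):
    """Decompose a label volume into per-frame :class:`Object2D` records.

    Each positive label's cross-section in a frame becomes one object whose
    id is the label value.  Returns a list of per-frame object lists, or a
    ``{label: [objects]}`` dict with ``group_by_cell``.
    """
    volume = np.asarray(volume)
    frames: List[List[Object2D]] = []
    by_cell: Dict[int, List[Object2D]] = {}
    for z in range(volume.shape[0]):
        frame_objs: List[Object2D] = []
        for lab in np.unique(volume[z]):
            if lab <= 0:
                continue
            rows, cols = np.nonzero(volume[z] == lab)
            pixels = frozenset(zip(rows.tolist(), cols.tolist()))
            obj = Object2D(
                id=int(lab),
                frame_index=z,
                pixels=pixels,
                centroid=(float(rows.mean()), float(cols.mean())),
                cls=SOMA_CANDIDATE,
            )
            frame_objs.append(obj)
            by_cell.setdefault(int(lab), []).append(obj)
        frames.append(frame_objs)
    return by_cell if group_by_cell else frames


def truth_objects(truth: GroundTruth) -> List[List[Object2D]]:
    """Per-frame object sets of the ground truth (ideal segmentation)."""
    return volume_to_objects(truth.label_volume)


def corrupt_with_oversegmentation(truth: GroundTruth, fraction: float, seed: int,
                                  mode: str = "split") -> List[List[Object2D]]:
    """Degrade the truth's 2-D objects to exercise error flagging.

    ``mode="split"`` cuts the chosen fraction of 2-D cross-sections in two
    through the centroid (over-segmentation); ``mode="fuse"`` unions each
    chosen object with its nearest same-frame neighbor (under-segmentation).
    ``fraction=0`` returns the truth objects unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("split", "fuse"):
        raise ValueError("mode must be 'split' or 'fuse'")
    rng = np.random.default_rng(seed)
    frames = truth_objects(truth)
    if fraction == 0:
        return frames
    flat = [(z, i) for z, objs in enumerate(frames) for i in range(len(objs))]
    n_pick = int(round(fraction * len(flat)))
    picked = set(
        tuple(flat[j]) for j in rng.choice(len(flat), size=min(n_pick, len(flat)), replace=False)
    )
    out: List[List[Object2D]] = []
    for z, objs in enumerate(frames):
        objs = list(objs)
        next_id = max((o.id for o in objs), default=0) + 1
        fused_away: set = set()
        result: List[Object2D] = []
        for i, obj in enumerate(objs):
            if i in fused_away:
                continue
            if (z, i) not in picked:
                result.append(obj)
                continue
            if mode == "split":
                col0 = obj.centroid[1]
                left = frozenset(p for p in obj.pixels if p[1] < col0)
                right = obj.pixels - left
                if not left or not right:
                    result.append(obj)
                    continue
                for half, oid in ((left, obj.id), (right, next_id)):
                    rows = [r for (r, _) in half]
                    cols = [c for (_, c) in half]
                    result.append(
                        replace(obj, id=oid, pixels=half,
                                centroid=(sum(rows) / len(rows), sum(cols) / len(cols)),
                                boundary=())
                    )
                next_id += 1
            else:  # fuse with nearest same-frame neighbor
                others = [
                    (j, o) for j, o in enumerate(objs)
                    if j > i and j not in fused_away  # not yet emitted
                ]
                if not others:
                    result.append(obj)
                    continue
                j, partner = min(
                    others, key=lambda jo: math.dist(obj.centroid, jo[1].centroid)
                )
                fused_away.add(j)
                merged = obj.pixels | partner.pixels
                rows = [r for (r, _) in merged]
                cols = [c for (_, c) in merged]
                result.append(
                    replace(obj, pixels=merged,
                            centroid=(sum(rows) / len(rows), sum(cols) / len(cols)),
                            boundary=())
                )
        out.append(result)
    return out
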