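# Methods

## Scope and model

`somaseg` locates neuronal cell bodies in a single-channel confocal z-stack
by segmenting every 2-D slice independently and stitching the per-slice
regions into 3-D cells. The approach assumes:

* somata are compact, roughly convex, and bright — at or near saturation
  when acquisition is tuned to capture fine neurites;
* neurites are thin (a few pixels) with mottled, spiny outlines, so a
  distance-transform-seeded watershed fractures them into fragments much
  smaller than any soma cross-section;
* a cell appears in several consecutive slices (typically 3–6 at common
  plane spacings), so anything confined to a single slice is an artifact or
  a neurite fragment.

2-D-then-stitch was chosen over direct 3-D segmentation because every
intermediate is a per-slice object that a user can inspect and correct, and
because the stitching step itself is where segmentation errors become
visible.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `T` (`threshold_pct`) | global intensity threshold, % of the maximum representable intensity | 95 | inclusive comparison; near-saturated somata tolerate a high global T |
| `α` (`alpha`) | pixel-area split between soma candidates (≥ α) and neurite fragments | 60 px | choose from the bimodal area histogram; equality counts as soma |
| `β` (`beta`) | overlap threshold for 3-D merge qualification, in [0, 1] | 0.70 | lower values make the error checks more sensitive |
| `transform` | distance metric seeding the watershed | euclidean | chessboard (`chebyshev`) is steadier on dense/clustered material |
| `erode` | one pass of 3×3 diamond erosion before the transform | off | for rampant clustering; shrinks every region by ~1 px |

Per-level reference operating points (the bundled validation study):
level 1 α=60, level 2 α=40, level 3 α=30 (chessboard), level 4 α=15 with
β=0.35 (chessboard); T=95 throughout. Erosion is not part of these
parameter rows and stays off unless requested.

## Overlap semantics in 3-D merging

The printed overlap measure is asymmetric:
`overlap(a, b) = |a ∩ b| / |a|`. Candidacy for merging is judged from *two
vantage points*: objects a (frame k) and b (frame k+1) qualify when
`|a ∩ b| ≥ β · min(|a|, |b|)`, i.e. the shared pixels exceed β of at least
one of the two areas. This single rule yields all the behaviours the method
relies on at the standard β = 0.7:

* a small terminal cross-section qualifies against the larger slice beneath
  it (its own fraction is ~1 even though the reverse fraction is small);
* two fragments of a fractured soma each lie almost wholly under the intact
  object in the adjacent frame, so both qualify — the forward projection
  sees multiple candidates, merges them and flags `forward_multi`;
* two somata fused into one object make both true objects qualify in the
  back projection — `reverse_multi`, flagged but never auto-split.

Chain extension (the actual 3-D merge) additionally requires **mutual
greatest overlap**: b must be a's greatest-overlap qualified candidate and
a must be b's greatest-overlap previous-frame partner, overlap ranked by
shared pixel count with ties broken toward the smaller object id.
"Unrequited overlap" — a prefers b, but b overlaps a third object more —
terminates a's chain. Requiring β in *both* directions instead would make
the bidirectional error checks vacuous for β > 0.5 (fractions against one
object sum to ≤ 1 over disjoint partners) and would forbid attaching any
cross-section smaller than β times its neighbor; the two-vantage-point
reading is the only one under which the documented operating points
function.

Objects with no qualified partner in either adjacent frame are removed as
artifacts; consequently every emitted `Cell3D` spans ≥ 2 consecutive
frames. When a forward conflict merges candidates, only candidates not
already consumed by another cell are united (all are flagged), so no pixel
is ever owned by two cells.

## Geometry statistics

Equivalent diameter per slice is `2√(area/π)`. Eccentricity comes from the
ellipse of the region's second central moments and concavity is defined as
`1 − area / convex_hull_area` (the source method names both without
formulas; these are the standard conventions and are documented as ours).
Manual boundaries are rasterized by pixel-center inclusion (a pixel belongs
if its center is inside or on the polygon, even-odd rule), so a side-10
axis-aligned square yields 11×11 = 121 pixels.

## Corrections

`add_cell`, `delete_cell`/`delete_object`, `merge_cells` and
`manual_boundary` mutate the 2-D object tables and then re-evaluate the 3-D
linkage by re-running the merge on the current tables. We deliberately
recompute globally rather than only around the edited frame: an edit at
frame z can legitimately break one chain into two (or join two) far from z,
and the merge is deterministic and cheap at these problem sizes, so global
recomputation buys correctness for free. Cell ids are renumbered by the
re-merge; callers track cells across edits by geometry, not id.

`resolve_flags_with_truth` stands in for the human reviewer of the flagged
locations: flagged cells matching no true soma are deleted, flagged
duplicates of an already-claimed soma are deleted, and a flagged cell
engulfing ≥ 2 true somata (≥ 50% of each) is split along the true
cross-sections — deletions and redraws a reviewer performs with the edit
API. Unflagged errors are never touched, mirroring a conservative
validation protocol in which reviewers may only act where the software
points.

## Synthetic phantoms

The generator emulates the four culture-complexity conditions: level 1 —
spherical somata, 0–2 neurites each, no clustering; level 2 — 2–5
neurites, slight clustering; level 3 — 5–9 neurites, 30% of somata placed
in contact clusters; level 4 — deformed (ellipsoid + surface bumps)
somata, 5–9 neurites, 30% clustering.

Key numeric choices, with rationale:

* **Soma radius 5.5–10 px** (default): cortical somata are 10–20 μm across
  and a 512-px field of ~460 μm gives 0.9 μm/px at 20×.
* **z spacing 2.5 px of depth per frame** (`z_scale`): radius 4–8 px somata
  then span ~3–6 slices, the typical occupancy for such acquisitions.
* **Brightness**: somata render at 270 and neurites at 260 pre-clip on the
  8-bit scale, i.e. above saturation; after additive Gaussian noise
  (σ = 5/255) and clipping, soma voxels sit at 255 — saturated, hole-free
  interiors, as in acquisition tuned for fine features. Background is 8.
* **Neurites** are persistent 3-D random walks (direction correlation 0.85)
  with per-step radius jitter of 0.35–1.15× the base half-width (widths
  1–3 px). The jitter is essential: smooth constant-width tubes do *not*
  fracture under watershed — they flood into the soma's basin and corrupt
  its overlap chain — whereas mottled tubes splinter into sub-α fragments,
  which is the morphology the classification step exploits.
* **Clustering** places the chosen fraction of somata at center distance
  0.85–1.1× the sum of radii from an anchor: touching or slightly
  indenting, like real solid cell bodies, producing fused 2-D
  cross-sections with necklines for the watershed to split.
* All randomness flows from one `numpy` generator seeded by `spec.seed`;
  identical specs give bit-identical stacks.

Ground truth labels soma voxels only (ties between overlapping somata go to
the nearer center), records per-cell centroid and radius, and refuses
configurations where a soma spans fewer than two frames.

What the phantoms do **not** model: the confocal point-spread function and
depth attenuation, autofluorescent background texture, brain-slice tissue
context, uneven labeling, and somata that are faint rather than saturated.
Passing the synthetic suite therefore demonstrates the correctness of the
algorithmic chain (threshold → transform → watershed → classification →
stitching → flagging → correction), not performance on degraded real
imagery; on real stacks the operating parameters must be chosen from the
histogram feedback as described above.

## Evaluation

`match_cells` assigns predicted to true cells greedily by descending shared
3-D voxel count (any positive overlap is matchable; ties toward lower ids);
unmatched predictions are false positives, unmatched true cells false
negatives. The headline score is the total error percentage
`100·(FP+FN)/actual` — both error types are counted because spurious and
missed cells cancel in a raw count comparison. `summarize_level` averages
*per-sample percentages* (not pooled counts) and reports the n−1 standard
deviation, at one decimal; a single sample reports SD 0.0 by convention.
The bundled reference validation counts reproduce all published summary
cells under exactly these conventions, which is how both conventions were
pinned down.

The "before correction" baseline used by the parameter sweep
(`stitch_forward_naive`) chains objects by best forward overlap alone —
no β, no mutuality, singletons kept — since the original baseline stage is
described only by name; it reproduces the characteristic count inflation
at permissive thresholds that the 3-D correction then removes.

## Problem sizes and known limitations

The test suite runs phantoms of 10–12 frames at 128–256 px and the
acceptance script six stacks of 16×512×512 with 20–60 somata each; both
finish in well under two minutes on one CPU.

Known limitations:

* Somata whose every cross-section falls below α are invisible to the
  method by construction; with α = 60 px this excludes cells under ~4.8 px
  radius at 2.5-px plane spacing. The synthetic accuracy surrogate over
  radius 4–8 px populations therefore loses part of the smallest-cell tail
  at the level-1 operating point (measured mean accuracy ≈ 90% versus
  ≈ 97% for realistic 5.5–10 px radii).
* Under-segmentation that produces no flag (two somata fused identically in
  every shared slice) is neither corrected nor reported.
* Flood tie-breaking on exactly symmetric plateaus follows the watershed
  implementation's deterministic insertion order rather than an explicit
  per-pixel rule.
* Label volumes cap at 65,535 cells (16-bit TIFF export).
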