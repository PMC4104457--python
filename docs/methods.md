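# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, in the package's own words. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate model

Volumes are scalar grids `data[x, y, z, c]` with 0-based, voxel-centered
coordinates: voxel `(i, j, k)` occupies `[i−0.5, i+0.5) × …`, so continuous
coordinates are meaningful everywhere and curve knots may be sub-voxel. On
disk, TIFF pages are Z, rows Y, columns X, channels samples-per-pixel;
NRRD goes through SimpleITK; the raw format stores little-endian C-order
`(Z, Y, X, C)` next to a JSON header.

The camera is orthographic only: every ray of one gesture is parallel, with
`screen = zoom · (R q)[:2] + pan` (screen origin top-left, y down). Rays are
clipped against the voxel-center bounding box `[0, dim−1]` per axis and
sampled at exactly 1.0-voxel steps from entry to exit, with trilinear
interpolation per channel. Clipping to voxel centers (rather than the outer
voxel faces) keeps interpolation well-defined without padding; with the
identity camera the samples then fall exactly on voxel centers.

## Geodesic metric and fast marching

The voxel graph uses 6/18/26-connectivity (default 18). Edge weight:
Euclidean step length times the mean of the endpoint intensity penalties
`g(i) = exp(λ (1 − norm(i))²)`, `λ = 10` by default, `norm` scaled by the
per-channel global min/max. On a flat image the normalized intensity is
taken as 1, so the metric degrades gracefully to Euclidean distance.
Multi-channel volumes drive the metric with a designated channel, by
default the per-voxel maximum across channels — the same thing a MIP viewer
shows the user.

The search is a best-first wavefront (cost-identical to Dijkstra on the
implicit graph) from a source voxel set until the first sink voxel is
finalized. Ties on the frontier pop the lowest `(z, y, x)` voxel, making
paths deterministic across platforms. The inner loop is a numba kernel with
a pure-Python heap fallback; the test suite proves cost equivalence against
an explicit-graph shortest path built independently with scipy on hundreds
of random volumes across all three connectivities. Search regions (boolean
masks or box unions) confine both the wavefront and the admissible
source/sink voxels.

## Pinpointing

`ppa_single` runs a progressive mean-shift along the ray: the range starts
as the whole sampled segment, is re-centered on the intensity-weighted
centroid and halved per iteration, and stops when the centroid moves less
than 0.5 voxel or at most 3 samples remain; the brightest sample of the
final range wins (ties → nearest the centroid). The centroid subtracts the
in-range minimum intensity first — on long rays the constant background
pedestal otherwise drags the centroid toward the middle of the ray and the
iteration can converge into the gap between two structures. A flat profile
returns `confident=False`. The halving schedule guarantees O(log n)
termination; returned locations sit on the ray's 1-voxel sample grid.

`ppa_c` runs the mean-shift per channel and keeps the candidate with the
largest raw voxel intensity (ties → lowest channel index), matching what a
user pointing at the brightest rendered structure means; a
per-channel-normalized comparison is available behind a flag, and a channel
can be fixed explicitly.

`ppa_n` maps a micro-stroke through the curve engine and returns the first
knot — the point on the ray of the stroke's starting location. Two
measures make it robust at very low SNR: (1) cursor samples closer than
3 px are collapsed, because near-duplicate rays give the first march
overlapping source and sink sets, and any shared bright voxel then forms a
degenerate zero-cost "path"; (2) the geodesic runs on a Gaussian-presmoothed
(σ = 1 voxel) copy of the volume, so coherent 3D structure outweighs
single-voxel noise spikes — at noise σ equal to half the signal amplitude,
isolated saturated speckle otherwise rivals a real fluorescent blob on raw
intensity. With `presmooth_sigma=0` the result is exactly the first knot of
the plain curve algorithm on the raw data.

## Curve drawing

**CDA1** chains range-restricted pinpoints (±30 voxels of the previous
knot); when no sample qualifies it takes the geometrically nearest sample,
which lets strokes continue through dark regions (the ROI-in-the-dark use
case) at the price of following the gesture rather than the signal.

**CDA2** marches from the voxels around the first ray to those around the
second ("around" = voxel centers within 1.0 voxel of the sampled ray
polyline), fixing both initial knots at once, then iterates single-source
marches to each next ray; the first hit is the next knot. The search
visits voxels only; the final knot is then corrected locally: an iterated
background-subtracted intensity centroid over a ±2-voxel neighborhood
(capped at 2 voxels of total motion so a knot cannot migrate to a different
structure). This per-step correction is what keeps stroke jitter and grid
discretization from accumulating along the curve.

**Globally optimal CDA2** first discards the dimmer half of the stroke's
cursor points (endpoints always kept so the curve spans the gesture), then
selects up to m = 5 candidate points per ray — ranked on a 3-sample moving
average of the ray profile so a broad tube crossing outranks an isolated
noise spike of similar height, mutually ≥ 2 voxels apart — computes exact
pairwise leg costs between consecutive rays' candidates with fast marching
confined to the margin-extended (5-voxel) box around both candidate sets,
and picks the minimum-total-cost chain by dynamic programming. The winning
chain is a minimum-cost *path*: when two consecutive chain points are far
apart (more than 2.5× the median leg, at least 4 voxels — i.e., the
preprocessing dropped a run of cursor points), the dense geodesic leg is
resampled (~3-voxel spacing) into the curve so it follows the signal
instead of cutting the straight chord. With m = 1 the variant degenerates
to greedy brightest-point chaining.

**Bounding-box-restricted CDA2** derives per-ray preliminary pinpoints,
builds consecutive-pair boxes expanded by a 5-voxel margin, and runs CDA2
inside their union. A margin that disconnects the region raises a no-curve
error rather than returning a wrong curve. Because the wavefront search is
already best-first, the unrestricted variant does not flood the volume on
clean data; the box restriction mainly caps worst-case work on cluttered or
noisy images, and the instrumented `visited` counter in the result lets
callers verify the saving.

**Smoothing.** The knot-count moving average (`smooth_curve`, window 5,
endpoints fixed, symmetric shrinking near the ends) is exact for densely
sampled strokes, where ~5 knots span ~5 voxels of arc. Simulated or
resampled strokes can space knots 5–20 voxels apart, where a knot-count
window is wrong in two ways: it shrinks curved sections toward their chord,
and it averages across large inter-knot gaps, dragging both flanking knots.
The CDA functions therefore default to a window measured in *arc length*
(~5 voxels wide): each interior knot becomes the mean of the finely
resampled knot polyline within ±2.5 voxels of arc. Collinear evenly spaced
knots are a fixed point of both smoothers. An explicit integer
`smooth_window` restores the knot-count behavior.

**Spatial divergence.** Both curves are resampled at 1-voxel arc length;
directed nearest-point distances (point-to-segment against the other
resampled polyline) are averaged in both directions and the mean of the two
directions reported, making the score symmetric and independent of knot
density. `max` is the largest nearest-point distance over both directions;
`fraction_visible` is the pooled fraction of samples at distance
≥ 2 voxels.

**Editing.** Dragging moves the grabbed knot by δ and its neighbors within
`radius` indices by δ scaled with a cosine falloff. Auto-joining inserts
the junction point into both segments whenever an endpoint comes within the
threshold (5 voxels, inclusive) of another segment, never moving existing
knots; joined segments share the junction knot exactly, and
`connected_components` counts the resulting structures.

## ROIs and the octree

A click ROI is a cube (default 33³) around the pinpointed location, spanning
`floor(edge/2)` voxels before the center voxel and the remainder after,
clipped to the volume. A stroke ROI is the clipped bounding box of the
curve's knots. A zoom ROI pinpoints along the four viewport corner rays
plus the center ray (corner rays alone often miss sparse signal), takes the
bounding box of the confident hits, and grows it to a minimum edge of 8
voxels; if every probe sees flat signal or misses, the geometric
frustum-volume intersection is returned with `confident=False`.

The octree halves X, Y and Z per level (2×2×2 block mean, rounding half-up
for integer dtypes; edge blocks average the voxels that exist; a max
aggregator is available for sparse signal) until the coarsest level fits
512×512×256 (configurable). Levels are stored as TIFF tiles named by their
voxel offset plus a JSON index; output bytes are a pure function of the
input. ROI resolution between levels scales coordinates by powers of two
(floor/ceil so the scaled box covers the original footprint) and walks only
the tile-grid range covering the box, so the work — exposed as
`tiles_examined` — depends on the ROI size alone, not on the total stack
size. Full-resolution loads are bit-identical to cropping the source.

## Phantoms

Intensity is `background + (peak − background) · exp(−d²/2σ²)` with `d`
the distance to the structure (computed against a 0.25-voxel-resampled
centerline via a KD-tree), plus optional additive Gaussian noise, clipped
to the dtype range; a fixed spec and seed is bit-reproducible. Defaults
mirror confocal practice: 8-bit data, peak 200 on background 20,
cross-section σ 1.5. Kinds: straight, bent (quadratic Bézier), helical
(radius/pitch/turns; default 1.5 turns), broken (arc-length gaps), blob,
and a two-tube occlusion scene where a brighter tract crosses the dim
target's projection along the view axis — the crossing matters, because two
tracts that coincide in projection everywhere are genuinely
indistinguishable from one viewpoint. Simulated strokes project
arc-length-uniform centerline points and add uniform ±jitter in screen
pixels (a shaking hand is a screen-space process).

What the phantoms do *not* emulate: anisotropic PSFs, depth-dependent
attenuation, photobleaching, autofluorescence texture, or the branching
complexity of real arbors. Passing tests therefore demonstrate the
correctness and noise behavior of the geometry engine, not segmentation
performance on real tissue.

## The precision benchmark

`vfinger.evaluation.run_precision_benchmark` measures tracing precision on
seven tracts in 64×64×48 volumes (fixed seeds 1–7): four bent tubes
extending mostly across the screen plane of their side-on base view, and
three sub-turn helical arcs (radius 9–11, pitch 28, 0.7 turns) viewed along
the helix axis, where the tangent keeps a constant ≥ 60° angle to the rays.
Base views are per tract because a user rotates the rendering until the
tract is visible before tracing; a tract running along the view axis is not
traceable by anyone. Each tract is traced from five rotations (0°, ±20°
about two screen axes) at two display zooms (2 and 4 px/voxel — tracing is
done on a magnified rendering, while hand jitter stays fixed at ±2 screen
pixels) with three jitter seeds: 210 curves, ≥ 20 000 resampled samples.
The globally optimal curve drawer runs with its defaults. Pooled statistics:
mean SD, % visible (≥ 2 voxel) samples, and the per-curve maximum averaged
over curves. The stroke-jitter seeds derive from the single `--seed`
argument; the phantom seeds are part of the benchmark definition.

## Known limitations

- The first knot of CDA2 on a self-overlapping projection (e.g. a
  multi-turn helix seen down its axis) can attach to either branch; all
  later knots follow it. This is an ambiguity of the inverse problem, not
  of the search.
- The geodesic metric assumes isotropic voxels; physical voxel size is
  carried as metadata but does not enter the edge weight.
- `ppa_c` compares raw intensities across channels; channels with wildly
  different dynamic ranges need the normalized mode or a fixed channel.
- The whole-volume fast march holds its distance and parent arrays in
  memory; for stacks beyond RAM the octree module is the intended path
  (march inside a loaded ROI), not a streaming search.
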