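# vfinger

**Virtual-finger 3D exploration of volumetric microscopy images:** map a
single 2D gesture — a mouse click, stroke, or zoom — performed on the 2D
maximum-intensity projection of a 3D image stack back into the volumetric
space, producing 3D points, curves, and regions of interest.

Biologists exploring fluorescence image stacks (neurons, vessels, bronchial
trees, labelled nuclei) spend most of their interaction time telling the
software *where* things are in 3D while only being able to point at a 2D
screen. This package solves that inverse problem for the three object types
that matter in practice:

- **Points** — one click pinpoints a cell or punctum (`ppa_c` for
  multi-channel data, `ppa_n` for heavily noisy data);
- **Curves** — one stroke traces a neurite or vessel in 3D (`cda1`,
  `cda2`, `cda2_global`, `cda2_bbox`), with editing primitives
  (smoothing, dragging, transforms, 5-voxel auto-joining) and the
  spatial-divergence score for comparing curves;
- **ROIs** — one click/stroke/zoom yields an axis-aligned 3D box
  (`roi_from_click`, `roi_from_stroke`, `roi_from_zoom`), which the octree
  module (`build_octree`, `resolve_roi`, `load_block`) turns into
  constant-work tile retrieval from stacks too large to load whole.

A deterministic phantom generator (`make_phantom`, `simulate_stroke`)
produces tubes, helices, blobs, occlusion scenes and simulated hand-jittered
strokes with analytic ground truth, so every claim is testable without
external data.

## The core algorithm

Each on-screen cursor location spawns a *shooting ray* orthogonal to the
screen, sampled at one-voxel spacing inside the volume. A click is resolved
by a progressive mean-shift along its ray; a stroke is resolved by chaining
shortest **geodesic** paths through the voxel graph, where the edge weight
between adjacent voxels *u*, *v* is

```
w(u, v) = ||u − v|| · ( g(I(u)) + g(I(v)) ) / 2
g(i)    = exp( λ · (1 − (i − I_min) / (I_max − I_min))² ),   λ = 10
```

so bright voxels are cheap and dark voxels exponentially expensive. A
fast-marching wavefront propagates from the last knot to the voxels around
the next ray without ever materializing the graph (18-connected by
default); the first sink it reaches becomes the next knot. The globally
optimal variant selects candidate points per ray and takes the
minimum-total-cost chain by dynamic programming, which makes the curve
robust to hand jitter and occlusion. Curves are compared with the
spatial-divergence (SD) score: resample both at one-voxel arc length and
average symmetrized nearest-point distances; samples ≥ 2 voxels apart count
as *visible* divergence.

## Worked example

`examples/02_trace_a_neurite.py` builds a noisy helical tract (peak 200 on
background 20, noise σ=30, 8-bit), simulates a 20-point stroke with 2 px of
hand jitter at 2× magnification, traces it, and scores the result:

```
stroke: 20 jittered screen points
curve : 10 knots -> traced_helix.swc
spatial divergence vs ground truth:
  mean 0.596 voxels   max 1.668 voxels   visible(>=2vx) 0.00%
```

The mean divergence is sub-voxel although the stroke was jittered and the
tract is buried in noise: stroke preprocessing keeps the brightest half of
the cursor points, the geodesic metric pins every leg to the bright tract,
and each knot is locally corrected before the curve is smoothed with a
~5-voxel moving window. The other examples cover pinpointing in
multi-channel data (`01`), the three ROI gestures (`03`), octree navigation
of large stacks (`04`), and curve proof-editing (`05`). A thin `vf` command
line (`vf pinpoint`, `vf curve`, `vf roi`, `vf sd`, `vf phantom make`,
`vf octree build|fetch`) exposes the same operations on serialized inputs
(TIFF/NRRD/raw volumes, JSON cameras and strokes, SWC curves, CSV markers).

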