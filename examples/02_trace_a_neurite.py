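"""One mouse stroke -> one 3D curve, scored against ground truth.

Generates a noisy helical tract (peak 200 on background 20, Gaussian noise
sigma 30), simulates a 20-point stroke with 2 pixels of hand jitter on the
projection, traces it with the globally optimal geodesic curve drawer, and
reports the spatial divergence from the analytic centerline.
"""

import numpy as np

from vfinger import (Camera, Curve, PhantomSpec, cda2_global, make_phantom,
                     simulate_stroke, spatial_divergence, write_swc)

spec = PhantomSpec("helix-tube", peak=200, background=20, sigma=1.5,
                   noise_sigma=30, seed=1,
                   params={"radius": 9, "pitch": 28, "turns": 0.7, "z0": 8.0})
ph = make_phantom(spec, (64, 64, 48))

cam = Camera.identity(zoom=2.0)          # tracing at 2x magnification
stroke = simulate_stroke(ph.centerline, cam, n_points=20, jitter_px=2.0, seed=7)

curve = cda2_global(stroke, cam, ph.volume)
sd = spatial_divergence(curve, Curve(ph.centerline))

write_swc(curve, "traced_helix.swc")
print(f"stroke: {len(stroke)} jittered screen points")
print(f"curve : {len(curve)} knots -> traced_helix.swc")
print(f"spatial divergence vs ground truth:")
print(f"  mean {sd['mean']:.3f} voxels   max {sd['max']:.3f} voxels   "
      f"visible(>=2vx) {100 * sd['fraction_visible']:.2f}%")
print()
print("Sub-voxel mean divergence despite the noise: the geodesic metric makes")
print("bright voxels cheap, so every leg of the curve snaps to the tract.")
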