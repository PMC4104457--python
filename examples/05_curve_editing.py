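"""Proof-editing primitives: smooth, drag, transform, and auto-join curves.

Emulates a typical correction session on a traced morphology: a missing
segment is drawn separately and automatically joined to the existing one
when its endpoint comes within 5 voxels.
"""

import numpy as np

from vfinger import Curve, drag_knot, join_segments, smooth_curve, transform_curve
from vfinger.curve import connected_components, mirror_transform

main_branch = Curve(np.stack([np.linspace(0, 30, 16), np.full(16, 10.0),
                              np.full(16, 5.0)], axis=1))
# a separately drawn segment whose start lies 3 voxels off the main branch
missing = Curve(np.stack([np.linspace(12, 22, 8), np.full(8, 13.0),
                          np.full(8, 5.0)], axis=1))

print(f"before join: {connected_components([main_branch, missing])} components")
joined = join_segments([main_branch, missing], threshold=5.0)
print(f"after join : {connected_components(joined)} component "
      f"(gap was 3 voxels <= the 5-voxel rule)")

dragged = drag_knot(main_branch, knot=8, delta=(0, 4.0, 0), radius=3)
moved = np.linalg.norm(dragged.knots - main_branch.knots, axis=1)
print(f"\ndrag knot 8 by 4 voxels with radius 3: displacements "
      f"{np.round(moved[5:12], 2)} (cosine falloff)")

smoothed = smooth_curve(dragged, window=5)
print(f"after smoothing, max deviation from the line drops "
      f"{np.abs(dragged.knots[:, 1] - 10).max():.2f} -> "
      f"{np.abs(smoothed.knots[1:-1, 1] - 10).max():.2f} voxels")

mirrored = transform_curve(main_branch, mirror_transform(axis=0, center=15.0))
print(f"\nmirror about x=15: first knot {main_branch.knots[0]} -> "
      f"{mirrored.knots[0]}")
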