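"""Click, stroke and zoom gestures -> 3D regions of interest.

Shows the three ROI generators on a blob-plus-tube scene: a one-click 33^3
cube, the bounding box of a one-stroke curve, and the box spanned by
pinpoints along the four corners of a zoomed viewport.
"""

import numpy as np

from vfinger import (Camera, PhantomSpec, Volume, crop, make_phantom,
                     roi_from_click, roi_from_stroke, roi_from_zoom,
                     simulate_stroke)

blob = make_phantom(PhantomSpec("blob", sigma=3.0, params={"center": (80, 40, 30)}),
                    (128, 96, 64))
tube = make_phantom(PhantomSpec("straight-tube",
                                params={"p0": (10, 70, 40), "p1": (110, 70, 40)}),
                    (128, 96, 64))
vol = Volume(np.maximum(blob.volume.data, tube.volume.data))
cam = Camera.identity()

click_box = roi_from_click((80, 40), cam, vol)
print(f"one click  -> cube {click_box.min_corner}..{click_box.max_corner} "
      f"({click_box.shape[0]}^3 voxels around the blob)")

stroke = simulate_stroke(tube.centerline, cam, 10, 0.0, seed=0)
stroke_box = roi_from_stroke(stroke, cam, vol)
print(f"one stroke -> box  {stroke_box.min_corner}..{stroke_box.max_corner} "
      f"(bounding box of the traced tube)")

zoom_box = roi_from_zoom([(70, 30), (95, 30), (95, 55), (70, 55)], cam, vol)
print(f"one zoom   -> box  {zoom_box.min_corner}..{zoom_box.max_corner} "
      f"(pinpoints along the viewport corner rays)")

sub = crop(vol, click_box)
print(f"\ncropped click-ROI sub-volume: dims {sub.dims}, "
      f"max intensity {int(sub.data.max())} (the blob core)")
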