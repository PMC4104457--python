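"""One-click, one-stroke, and one-zoom 3D region-of-interest generation.

A click pinpoints a 3D location and wraps a cube-shaped window (default
33^3 voxels) around it; a stroke takes the bounding box of the generated
curve; a zoom gesture pinpoints along the four viewport-corner rays (plus
the center ray for robustness) and takes the bounding box of the hits.
All boxes are half-open ``[min, max)`` in integer voxel coordinates and
clipped to the volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curve import cda1, cda2
from .errors import NoPointError
from .pinpoint import ppa_c, ppa_n
from .projection import Camera, Stroke, screen_to_ray
from .volume import Volume

__all__ = ["Box3D", "roi_from_click", "roi_from_stroke", "roi_from_zoom", "crop"]


@dataclass
class Box3D:
    """Half-open axis-aligned voxel box ``[min_corner, max_corner)``."""

    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]
    confident: bool = True

    def __post_init__(self) -> None:
        mn = tuple(int(v) for v in self.min_corner)
        mx = tuple(int(v) for v in self.max_corner)
        if any(a >= b for a, b in zip(mn, mx)):
            raise ValueError(f"empty box {mn}..{mx}")
        self.min_corner, self.max_corner = mn, mx

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.min_corner, self.max_corner))

    @property
    def n_voxels(self) -> int:
        s = self.shape
        return s[0] * s[1] * s[2]

    def contains(self, p) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(
            np.all(p >= np.asarray(self.min_corner) - 0.5)
            and np.all(p < np.asarray(self.max_corner) - 0.5)
        )

    def to_json(self) -> dict:
        return {"min": list(self.min_corner), "max": list(self.max_corner)}

    @classmethod
    def from_json(cls, obj) -> "Box3D":
        if isinstance(obj, (str, Path)):
            obj = json.loads(Path(obj).read_text())
        return cls(tuple(obj["min"]), tuple(obj["max"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))


def _clip_box(lo, hi, dims) -> Box3D:
    dims = np.asarray(dims, dtype=int)
    lo = np.clip(np.asarray(lo, dtype=int), 0, dims - 1)
    hi = np.clip(np.asarray(hi, dtype=int), 1, dims)
    hi = np.maximum(hi, lo + 1)
    return Box3D(tuple(lo), tuple(hi))


def _cube_around(center, edge: int, dims) -> Box3D:
    """Cube of side ``edge`` around the voxel containing ``center``: the cube
    spans floor(edge/2) voxels before the center voxel and the rest after."""
    c = np.round(np.asarray(center, dtype=float)).astype(int)
    lo = c - edge // 2
    return _clip_box(lo, lo + edge, dims)


def roi_from_click(
    p, cam: Camera, vol: Volume, edge: int = 33, stroke: Stroke = None
) -> Box3D:
    """Cube ROI (default 33^3) around the pinpointed click location.

    When a short ``stroke`` is supplied the noise-robust pinpoint is used to
    locate the center instead of the plain multi-channel one.
    """
    if edge < 1:
        raise ValueError("edge must be >= 1")
    if stroke is not None and len(stroke) >= 2:
        res = ppa_n(stroke, cam, vol)
    else:
        res = ppa_c(p, cam, vol)
    box = _cube_around(res.location, edge, vol.dims)
    assert box.contains(res.location) or not vol.contains(res.location)
    return box


def roi_from_stroke(s: Stroke, cam: Camera, vol: Volume, algo: str = "cda2") -> Box3D:
    """Bounding box of the curve generated from the stroke (CDA1 or CDA2)."""
    if algo == "cda1":
        curve = cda1(s, cam, vol)
    elif algo == "cda2":
        curve = cda2(s, cam, vol)
    else:
        raise ValueError("algo must be 'cda1' or 'cda2'")
    k = curve.knots
    # bounds of the voxels containing the extreme knots (voxel-centered grid)
    lo = np.round(k.min(axis=0)).astype(int)
    hi = np.round(k.max(axis=0)).astype(int) + 1
    return _clip_box(lo, hi, vol.dims)


def _frustum_box(corners, cam: Camera, vol: Volume) -> Box3D:
    """Geometric fallback: the viewport's orthographic frustum clipped to the
    volume, taken as the bounding box of the corner rays' entry/exit points."""
    pts = []
    for p in corners:
        ray = screen_to_ray(p, cam, vol)
        if not ray.is_empty:
            pts.append(ray.samples[0])
            pts.append(ray.samples[-1])
    if not pts:
        return Box3D((0, 0, 0), tuple(vol.dims), confident=False)
    pts = np.array(pts)
    box = _clip_box(np.floor(pts.min(axis=0)), np.floor(pts.max(axis=0)) + 1, vol.dims)
    box.confident = False
    return box


def roi_from_zoom(viewport, cam: Camera, vol: Volume, min_edge: int = 8) -> Box3D:
    """ROI for a zoom gesture: pinpoint along the viewport corner rays (and
    the center ray) and take the bounding box of the hits, grown to a minimum
    edge.  Falls back to the geometric frustum/volume box (``confident=False``)
    when every ray misses or sees flat signal."""
    corners = np.asarray(viewport, dtype=float).reshape(-1, 2)
    if corners.shape[0] != 4 or np.unique(corners, axis=0).shape[0] != 4:
        raise ValueError("viewport needs 4 distinct corners")
    # degenerate viewport: all corners collinear
    v = corners[1:] - corners[0]
    cross = v[0, 0] * v[1:, 1] - v[0, 1] * v[1:, 0]
    if np.all(np.abs(cross) < 1e-9):
        raise ValueError("viewport corners are collinear")
    probes = list(corners) + [corners.mean(axis=0)]
    hits = []
    for p in probes:
        try:
            res = ppa_c(p, cam, vol)
        except NoPointError:
            continue
        if res.confident:
            hits.append(res.location)
    if not hits:
        box = _frustum_box(corners, cam, vol)
    else:
        pts = np.array(hits)
        box = _clip_box(np.round(pts.min(axis=0)), np.round(pts.max(axis=0)) + 1, vol.dims)
    # grow to the minimum edge, clipped
    lo = np.asarray(box.min_corner)
    hi = np.asarray(box.max_corner)
    for a in range(3):
        edge = hi[a] - lo[a]
        want = min(min_edge, vol.dims[a])
        if edge < want:
            grow = want - edge
            lo[a] -= grow // 2
            hi[a] += grow - grow // 2
            if lo[a] < 0:
                hi[a] -= lo[a]
                lo[a] = 0
            if hi[a] > vol.dims[a]:
                lo[a] -= hi[a] - vol.dims[a]
                hi[a] = vol.dims[a]
    out = Box3D(tuple(lo), tuple(hi), confident=box.confident)
    return out


def crop(vol: Volume, box: Box3D) -> Volume:
    """The sub-volume covered by ``box``."""
    a, b = box.min_corner, box.max_corner
    return Volume(vol.data[a[0]:b[0], a[1]:b[1], a[2]:b[2], :].copy(),
                  voxel_size=vol.voxel_size)
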