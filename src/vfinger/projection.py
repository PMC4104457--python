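"""Orthographic camera model, shooting rays, strokes, and MIP rendering.

The camera is purely orthographic: all shooting rays generated from one view
are parallel (one ray per on-screen cursor location).  Screen coordinates have
their origin at the top-left corner, x to the right and y down; ``zoom`` is
screen pixels per voxel and ``pan`` a 2D screen offset.

A point ``q`` in volume coordinates projects to::

    screen = zoom * (R @ q)[:2] + pan

with ``R`` the 3x3 orthonormal camera rotation (rows: screen axes u, v and the
view direction w, all in volume coordinates).  ``screen_to_ray`` inverts this:
the ray through screen point ``p`` travels along ``w`` and is sampled at
exactly one-voxel spacing between its entry and exit through the volume's
voxel-center bounding box ``[0, dim-1]`` per axis, front to back.  Intensities
are sampled by trilinear interpolation per channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume

__all__ = ["Camera", "Ray", "Stroke", "screen_to_ray", "project_point", "render_mip"]

_EPS = 1e-9


@dataclass
class Camera:
    rotation: np.ndarray  # (3, 3), rows = u, v, w in volume coordinates
    zoom: float = 1.0
    pan: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("camera rotation must be orthonormal (R^T R = I)")
        if not self.zoom > 0:
            raise ValueError("zoom must be > 0")
        self.rotation = R
        self.pan = np.asarray(self.pan, dtype=float).reshape(2)

    @property
    def view_dir(self) -> np.ndarray:
        """Unit view direction w in volume coordinates."""
        return self.rotation[2]

    @classmethod
    def identity(cls, zoom: float = 1.0, pan=(0.0, 0.0)) -> "Camera":
        return cls(np.eye(3), zoom, np.asarray(pan, dtype=float))

    def to_json(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "zoom": float(self.zoom),
            "pan": [float(v) for v in self.pan],
        }

    @classmethod
    def from_json(cls, obj) -> "Camera":
        if isinstance(obj, (str, Path)):
            obj = json.loads(Path(obj).read_text())
        return cls(
            np.asarray(obj["rotation"], dtype=float).reshape(3, 3),
            float(obj.get("zoom", 1.0)),
            np.asarray(obj.get("pan", (0.0, 0.0)), dtype=float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))


@dataclass
class Ray:
    """A shooting ray with one-voxel-spaced in-volume samples.

    ``samples`` is (N, 3) continuous positions, front to back; ``intensities``
    is (N, C).  N == 0 flags a ray that misses the volume entirely (curve
    algorithms treat it as a skip, not an error).
    """

    origin: np.ndarray
    direction: np.ndarray
    samples: np.ndarray
    intensities: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.samples.shape[0] == 0

    def max_intensity(self) -> float:
        """Brightest sampled intensity across all channels (-inf when empty)."""
        if self.is_empty:
            return float("-inf")
        return float(self.intensities.max())


@dataclass
class Stroke:
    """Ordered 2D screen points sampled from one mouse gesture."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.shape[0] < 1:
            raise ValueError("stroke needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("stroke coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_json(self) -> dict:
        return {"points": [[float(x), float(y)] for x, y in self.points]}

    @classmethod
    def from_json(cls, obj) -> "Stroke":
        if isinstance(obj, (str, Path)):
            obj = json.loads(Path(obj).read_text())
        return cls(np.asarray(obj["points"], dtype=float))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))


def project_point(q, cam: Camera) -> np.ndarray:
    """Orthographic projection of a 3D volume point onto the screen."""
    q = np.asarray(q, dtype=float).reshape(3)
    return cam.zoom * (cam.rotation @ q)[:2] + cam.pan


def _ray_base(p, cam: Camera) -> np.ndarray:
    """A 3D point whose projection is screen point ``p`` (view depth 0)."""
    p = np.asarray(p, dtype=float).reshape(2)
    view = np.array([*(p - cam.pan) / cam.zoom, 0.0])
    return cam.rotation.T @ view


def _clip_ray(base: np.ndarray, w: np.ndarray, dims) -> tuple[float, float, bool]:
    """Slab-clip the line ``base + t*w`` against [0, dim-1] per axis."""
    lo, hi = -np.inf, np.inf
    for a in range(3):
        if abs(w[a]) < _EPS:
            if not (-_EPS <= base[a] <= dims[a] - 1 + _EPS):
                return 0.0, -1.0, False
        else:
            t0 = (0.0 - base[a]) / w[a]
            t1 = (dims[a] - 1.0 - base[a]) / w[a]
            lo = max(lo, min(t0, t1))
            hi = min(hi, max(t0, t1))
    return lo, hi, hi >= lo - _EPS


def _sample_channels(vol: Volume, pts: np.ndarray) -> np.ndarray:
    """Trilinear per-channel interpolation at (N, 3) continuous positions."""
    out = np.empty((pts.shape[0], vol.n_channels), dtype=float)
    coords = pts.T  # (3, N) in (x, y, z) order matching the (X, Y, Z) arrays
    for c in range(vol.n_channels):
        out[:, c] = map_coordinates(
            vol.channel(c).astype(float), coords, order=1, mode="nearest"
        )
    return out


def screen_to_ray(p, cam: Camera, vol: Volume) -> Ray:
    """Shooting ray through screen point ``p``, orthogonal to the screen.

    Samples start at the volume-entry point and step exactly 1.0 voxel along
    the view direction until exit.  A ray that misses the volume gets empty
    samples (``Ray.is_empty``) rather than raising.
    """
    w = cam.view_dir
    base = _ray_base(p, cam)
    lo, hi, hit = _clip_ray(base, w, vol.dims)
    if not hit:
        return Ray(base, w, np.empty((0, 3)), np.empty((0, vol.n_channels)))
    n = int(np.floor(hi - lo + _EPS)) + 1
    ts = lo + np.arange(n)
    pts = base[np.newaxis] + ts[:, np.newaxis] * w[np.newaxis]
    pts = np.clip(pts, 0.0, np.asarray(vol.dims, dtype=float) - 1.0)
    return Ray(base, w, pts, _sample_channels(vol, pts))


def render_mip(vol: Volume, cam: Camera, size) -> np.ndarray:
    """Maximum intensity projection: ``(H, W, C)`` image, row j = screen y.

    Each pixel is the per-channel maximum along its shooting ray; rays that
    miss the volume render as 0.
    """
    w_px, h_px = int(size[0]), int(size[1])
    if w_px < 1 or h_px < 1:
        raise ValueError("render size must be >= 1x1")
    xs, ys = np.meshgrid(np.arange(w_px), np.arange(h_px))
    screen = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    view = np.concatenate(
        [(screen - cam.pan) / cam.zoom, np.zeros((screen.shape[0], 1))], axis=1
    )
    base = view @ cam.rotation  # == (R.T @ view.T).T
    w = cam.view_dir
    dims = np.asarray(vol.dims, dtype=float)

    lo = np.full(base.shape[0], -np.inf)
    hi = np.full(base.shape[0], np.inf)
    miss = np.zeros(base.shape[0], dtype=bool)
    for a in range(3):
        if abs(w[a]) < _EPS:
            miss |= (base[:, a] < -_EPS) | (base[:, a] > dims[a] - 1 + _EPS)
        else:
            t0 = (0.0 - base[:, a]) / w[a]
            t1 = (dims[a] - 1.0 - base[:, a]) / w[a]
            lo = np.maximum(lo, np.minimum(t0, t1))
            hi = np.minimum(hi, np.maximum(t0, t1))
    miss |= hi < lo - _EPS

    out = np.zeros((screen.shape[0], vol.n_channels), dtype=float)
    live = ~miss
    if np.any(live):
        lo_l, hi_l, base_l = lo[live], hi[live], base[live]
        n_max = int(np.floor((hi_l - lo_l).max() + _EPS)) + 1
        ts = lo_l[:, np.newaxis] + np.arange(n_max)[np.newaxis, :]
        valid = ts <= hi_l[:, np.newaxis] + _EPS
        pts = base_l[:, np.newaxis, :] + ts[..., np.newaxis] * w
        pts = np.clip(pts, 0.0, dims - 1.0)
        flat = pts.reshape(-1, 3)
        vals = _sample_channels(vol, flat).reshape(pts.shape[0], n_max, -1)
        vals[~valid] = -np.inf
        out[live] = vals.max(axis=1)
        out[live] = np.where(np.isfinite(out[live]), out[live], 0.0)
    return out.reshape(h_px, w_px, vol.n_channels)
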