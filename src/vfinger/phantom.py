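"""Deterministic synthetic phantoms with analytic ground truth.

Every test input is generated, never loaded: tubular tracts with Gaussian
cross-sections (straight, bent, helical, broken), blobs, and occlusion
scenes, plus simulated on-screen strokes.  Intensity is::

    I(x) = background + peak * exp(-d(x)^2 / (2 sigma^2))

where ``d`` is the distance from voxel ``x`` to the structure's centerline
(or center), with optional additive Gaussian noise clipped to the dtype
range.  The same spec and seed always produce a bit-identical volume, and
the analytic centerline is returned alongside so spatial divergence against
ground truth is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.spatial import cKDTree

from .curve import resample_polyline
from .errors import PhantomError
from .projection import Camera, Stroke, project_point
from .volume import Volume

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "simulate_stroke"]

_KINDS = ("straight-tube", "helix-tube", "bent-tube", "blob",
          "two-tube-occlusion", "broken-tube")


@dataclass
class PhantomSpec:
    kind: str
    peak: float = 200.0
    background: float = 20.0
    sigma: float = 1.5
    noise_sigma: float = 0.0
    seed: int = 0
    dtype: str = "uint8"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise PhantomError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if not self.peak > self.background >= 0:
            raise PhantomError("need peak > background >= 0")
        if not self.sigma > 0:
            raise PhantomError("cross-section sigma must be > 0")


@dataclass
class Phantom:
    volume: Volume
    centerline: np.ndarray  # (M, 3) polyline, or (1, 3) for a blob
    spec: PhantomSpec
    extras: dict = field(default_factory=dict)

    @property
    def center(self) -> np.ndarray:
        return self.centerline.mean(axis=0)


def _helix(dims, params) -> np.ndarray:
    d = np.asarray(dims, dtype=float)
    radius = float(params.get("radius", 8.0))
    pitch = float(params.get("pitch", 10.0))
    turns = float(params.get("turns", 1.5))
    z0 = float(params.get("z0", 4.0))
    z1 = float(params.get("z1", min(z0 + turns * pitch, d[2] - 5.0)))
    phase = float(params.get("phase", 0.0))
    cx, cy = params.get("center", (d[0] / 2.0, d[1] / 2.0))
    z = np.arange(z0, z1, 0.25)
    theta = phase + 2.0 * math.pi * (z - z0) / pitch
    return np.stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta), z], axis=1)


def _bent(dims, params) -> np.ndarray:
    d = np.asarray(dims, dtype=float)
    p0 = np.asarray(params.get("p0", (4.0, d[1] * 0.3, d[2] / 2.0)), dtype=float)
    p1 = np.asarray(params.get("p1", (d[0] / 2.0, d[1] * 0.8, d[2] * 0.3)), dtype=float)
    p2 = np.asarray(params.get("p2", (d[0] - 5.0, d[1] * 0.3, d[2] * 0.7)), dtype=float)
    t = np.linspace(0.0, 1.0, 400)[:, None]
    bez = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    return resample_polyline(bez, 0.25)


def _straight(dims, params) -> np.ndarray:
    d = np.asarray(dims, dtype=float)
    p0 = np.asarray(params.get("p0", (4.0, d[1] / 2.0, d[2] / 2.0)), dtype=float)
    p1 = np.asarray(params.get("p1", (d[0] - 5.0, d[1] / 2.0, d[2] / 2.0)), dtype=float)
    n = max(2, int(np.linalg.norm(p1 - p0) / 0.25))
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0 + t * (p1 - p0)


def _centerline(kind, dims, params) -> np.ndarray:
    if kind == "blob":
        d = np.asarray(dims, dtype=float)
        return np.asarray(params.get("center", d / 2.0), dtype=float)[None, :]
    if kind == "helix-tube":
        return _helix(dims, params)
    if kind == "bent-tube":
        return _bent(dims, params)
    return _straight(dims, params)  # straight-tube / broken-tube default


def _drop_gaps(line: np.ndarray, gaps) -> np.ndarray:
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    frac = arc / arc[-1] if arc[-1] > 0 else arc
    keep = np.ones(line.shape[0], dtype=bool)
    for a, b in gaps:
        keep &= ~((frac >= a) & (frac <= b))
    return line[keep]


def _field(line: np.ndarray, grid: np.ndarray, peak: float, sigma: float) -> np.ndarray:
    tree = cKDTree(line)
    d, _ = tree.query(grid, k=1)
    return peak * np.exp(-(d**2) / (2.0 * sigma**2))


def make_phantom(spec: PhantomSpec, dims) -> Phantom:
    """Render a phantom volume and return it with its ground-truth geometry."""
    dims = tuple(int(v) for v in dims)
    if min(dims) < 3:
        raise PhantomError(f"dims {dims} too small for any phantom")
    extras: dict = {}

    if spec.kind == "two-tube-occlusion":
        # dim (optionally broken) target tract behind a brighter occluder;
        # the occluder crosses the target's projection along the default
        # (z) view axis, hiding its middle in a MIP
        d = np.asarray(dims, dtype=float)
        z_target = float(spec.params.get("z_target", d[2] * 0.7))
        z_front = float(spec.params.get("z_front", d[2] * 0.3))
        y = float(spec.params.get("y", d[1] / 2.0))
        target = _straight(dims, {"p0": (4.0, y, z_target), "p1": (d[0] - 5.0, y, z_target)})
        front = _straight(dims, {"p0": (4.0, 6.0, z_front), "p1": (d[0] - 5.0, d[1] - 7.0, z_front)})
        gaps = spec.params.get("gaps", [(0.45, 0.55)])
        target_drawn = _drop_gaps(target, gaps) if gaps else target
        peak_front = float(spec.params.get("peak_front", 240.0))
        structures = [(target_drawn, spec.peak), (front, peak_front)]
        truth = target
        extras["front_centerline"] = front
    else:
        truth = _centerline(spec.kind, dims, spec.params)
        drawn = truth
        if spec.kind == "broken-tube":
            drawn = _drop_gaps(truth, spec.params.get("gaps", [(0.4, 0.55)]))
        structures = [(drawn, spec.peak)]

    margin = 1.0
    hi = np.asarray(dims, dtype=float) - 1.0
    for line, _ in structures:
        if np.any(line < -margin) or np.any(line > hi + margin):
            raise PhantomError(f"{spec.kind} geometry exceeds dims {dims}")

    xs, ys, zs = np.meshgrid(*(np.arange(n, dtype=float) for n in dims), indexing="ij")
    grid = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    img = np.full(grid.shape[0], float(spec.background))
    for line, peak in structures:
        img += _field(line, grid, peak - spec.background, spec.sigma)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    dtype = np.dtype(spec.dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        img = np.clip(np.round(img), info.min, info.max)
    data = img.reshape(dims).astype(dtype)
    return Phantom(Volume(data), truth, spec, extras)


def simulate_stroke(
    centerline: np.ndarray,
    cam: Camera,
    n_points: int = 20,
    jitter_px: float = 0.0,
    seed: int = 0,
) -> Stroke:
    """Project ``n_points`` arc-length-equally-spaced centerline points and
    add uniform jitter within +-``jitter_px`` screen pixels (a shaking hand)."""
    if n_points < 2:
        raise ValueError("a stroke needs at least 2 points")
    line = np.atleast_2d(np.asarray(centerline, dtype=float))
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    ts = np.linspace(0.0, arc[-1], n_points)
    pts3 = np.stack([np.interp(ts, arc, line[:, a]) for a in range(3)], axis=1)
    screen = np.array([project_point(q, cam) for q in pts3])
    if jitter_px > 0:
        rng = np.random.default_rng(seed)
        screen = screen + rng.uniform(-jitter_px, jitter_px, size=screen.shape)
    return Stroke(screen)
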