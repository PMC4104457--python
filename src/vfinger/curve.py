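"""One-stroke 3D curve generation and curve utilities.

Two curve-drawing algorithm families map a single 2D mouse stroke to a 3D
curve, one knot per shooting ray:

* **CDA1** chains range-restricted pinpoints: the first knot comes from the
  multi-channel pinpoint on the first ray, and each next knot is the
  mean-shift peak among the next ray's samples within +-30 voxels of the
  previous knot (falling back to the geometrically nearest sample in dark
  regions).  Fast, but it follows the gesture rather than the signal.

* **CDA2** chains geodesic shortest paths: fast marching runs from the last
  knot to the voxels immediately around the next ray, and the first hit
  becomes the next knot.  The initial pair of knots comes from a single
  march between the first two rays' voxel sets, and the finished knot chain
  is smoothed with a small moving window.  Variants: ``cda2_global``
  (dynamic-programming minimum-total-cost chain over per-ray candidate
  points, robust to jittered strokes) and ``cda2_bbox`` (search confined to
  margin-extended boxes around preliminary pinpoints).

``spatial_divergence`` scores two curves by resampling both at one-voxel arc
length and averaging symmetrized nearest-point distances; distances of at
least 2 voxels count as "visible" divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyStrokeError, MetricError, NoCurveError, NoPathError
from .geodesic import GeodesicParams, fast_march, geodesic_costs
from .projection import Camera, Ray, Stroke, screen_to_ray
from .volume import IntensityRange, Volume

__all__ = [
    "Curve",
    "SearchRegion",
    "preprocess_stroke",
    "cda1",
    "cda2",
    "cda2_global",
    "cda2_bbox",
    "smooth_curve",
    "spatial_divergence",
    "transform_curve",
    "drag_knot",
    "join_segments",
    "connected_components",
    "resample_polyline",
    "read_swc",
    "write_swc",
    "similarity_transform",
    "mirror_transform",
]


@dataclass
class Curve:
    """Ordered 3D knots, optionally with per-knot generating-ray indices."""

    knots: np.ndarray
    ray_index: Optional[list[int]] = None
    dense_path: Optional[np.ndarray] = None
    cost: Optional[float] = None
    visited: int = 0

    def __post_init__(self) -> None:
        self.knots = np.atleast_2d(np.asarray(self.knots, dtype=float))
        if self.knots.shape[1] != 3:
            raise ValueError("knots must be (N, 3)")
        if self.ray_index is not None:
            idx = list(self.ray_index)
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("ray_index must be strictly increasing")
            self.ray_index = idx

    def __len__(self) -> int:
        return self.knots.shape[0]


@dataclass
class SearchRegion:
    """Search confinement for CDA2: the whole ray/volume overlap, or a union
    of margin-extended boxes (half-open integer corners)."""

    kind: str = "whole-overlap"
    boxes: list = field(default_factory=list)
    margin: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("whole-overlap", "bounding-boxes"):
            raise ValueError("kind must be 'whole-overlap' or 'bounding-boxes'")
        if self.kind == "bounding-boxes" and not self.boxes:
            raise ValueError("bounding-boxes region needs at least one box")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


# ---------------------------------------------------------------------------
# Geometry helpers


def _point_to_segments(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point (N, 3) to polyline ``poly`` (M, 3)."""
    points = np.atleast_2d(points)
    if poly.shape[0] == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]  # (S, 3)
    ab = poly[1:] - a
    ab2 = (ab**2).sum(axis=1)
    ab2[ab2 == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]  # (N, S, 3)
    t = np.clip((ap * ab[None]).sum(axis=2) / ab2[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def _nearest_on_polyline(point, poly: np.ndarray):
    """(distance, nearest point, insertion index) of ``point`` on ``poly``."""
    point = np.asarray(point, dtype=float)
    if poly.shape[0] == 1:
        return float(np.linalg.norm(point - poly[0])), poly[0].copy(), 1
    a = poly[:-1]
    ab = poly[1:] - a
    ab2 = (ab**2).sum(axis=1)
    ab2[ab2 == 0] = 1.0
    t = np.clip(((point - a) * ab).sum(axis=1) / ab2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(point - proj, axis=1)
    s = int(np.argmin(d))
    return float(d[s]), proj[s].copy(), s + 1


def resample_polyline(knots: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc length (endpoints included)."""
    knots = np.atleast_2d(np.asarray(knots, dtype=float))
    seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return knots[:1].copy()
    n = max(2, int(math.floor(total / spacing)) + 1)
    ts = np.linspace(0.0, total, n)
    return np.stack([np.interp(ts, arc, knots[:, a]) for a in range(3)], axis=1)


def _ray_sink_voxels(ray: Ray, dims) -> np.ndarray:
    """Voxels whose center lies within 1.0 voxel of the sampled ray polyline."""
    dims = np.asarray(dims, dtype=int)
    base = np.round(ray.samples).astype(int)
    offs = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    cand = (base[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    cand = cand[np.all((cand >= 0) & (cand < dims), axis=1)]
    cand = np.unique(cand, axis=0)
    d = _point_to_segments(cand.astype(float), ray.samples)
    return cand[d <= 1.0]


# ---------------------------------------------------------------------------
# Stroke preprocessing


def _stroke_rays(s: Stroke, cam: Camera, vol: Volume) -> list[Ray]:
    return [screen_to_ray(p, cam, vol) for p in s.points]


def preprocess_stroke(s: Stroke, cam: Camera, vol: Volume) -> Stroke:
    """Keep the 50% of on-screen points whose rays hit the brightest voxels.

    A mouse has an uneven sampling rate and hands shake; only
    ``ceil(N/2)`` points with the highest maximum sampled ray intensity are
    kept, in their original order, and the first and last points are always
    retained so the curve spans the whole gesture.
    """
    if len(s) < 2:
        raise ValueError("preprocessing needs a stroke of >= 2 points")
    rays = _stroke_rays(s, cam, vol)
    bright = np.array([r.max_intensity() for r in rays])
    if not np.any(np.isfinite(bright)):
        raise EmptyStrokeError("every ray of the stroke misses the volume")
    n = len(s)
    keep_n = max(2, math.ceil(n / 2))
    keep = {0, n - 1}
    interior = sorted(range(1, n - 1), key=lambda i: -bright[i])
    keep.update(interior[: keep_n - 2])
    idx = sorted(keep)
    return Stroke(s.points[idx])


# ---------------------------------------------------------------------------
# CDA1


def _ppa_on_ray(ray: Ray, sel: Optional[np.ndarray] = None):
    """Multi-channel pinpoint on an existing ray, optionally restricted to a
    boolean sample selection.  Returns (sample index, channel, intensity)."""
    positions = np.arange(ray.samples.shape[0], dtype=float)
    if sel is None:
        sel = np.ones(ray.samples.shape[0], dtype=bool)
    idx_sel = np.flatnonzero(sel)
    best = None
    from .pinpoint import _mean_shift_peak

    for c in range(ray.intensities.shape[1]):
        local, _ = _mean_shift_peak(positions[sel], ray.intensities[sel, c])
        gi = int(idx_sel[local])
        inten = float(ray.intensities[gi, c])
        if best is None or inten > best[2]:
            best = (gi, c, inten)
    return best


def cda1(s: Stroke, cam: Camera, vol: Volume, range_voxels: float = 30.0) -> Curve:
    """Chain range-restricted pinpoints (fast; follows the gesture in the dark).

    The first knot is the multi-channel pinpoint on the first ray; each next
    knot is pinpointed among the next ray's samples within ``range_voxels``
    (3D distance, default +-30) of the previous knot.  When no sample
    qualifies the geometrically nearest sample is taken, which lets strokes
    continue through dark regions (the ROI-in-the-dark use case).
    """
    if len(s) < 2:
        raise NoCurveError("curve generation needs a stroke of >= 2 points")
    rays = _stroke_rays(s, cam, vol)
    if rays[0].is_empty:
        raise NoCurveError("first ray misses the volume")
    gi, _, _ = _ppa_on_ray(rays[0])
    knots = [rays[0].samples[gi]]
    ray_index = [0]
    for k, ray in enumerate(rays[1:], start=1):
        if ray.is_empty:
            continue
        prev = knots[-1]
        d = np.linalg.norm(ray.samples - prev, axis=1)
        sel = d <= range_voxels
        if np.any(sel):
            gi, _, _ = _ppa_on_ray(ray, sel)
        else:
            gi = int(np.argmin(d))
        knots.append(ray.samples[gi])
        ray_index.append(k)
    return Curve(np.array(knots), ray_index=ray_index)


# ---------------------------------------------------------------------------
# CDA2 family


def _live_rays(s: Stroke, cam: Camera, vol: Volume):
    rays = _stroke_rays(s, cam, vol)
    live = [(i, r) for i, r in enumerate(rays) if not r.is_empty]
    if len(live) < 2:
        raise NoCurveError("fewer than two rays intersect the volume")
    return live


def _metric_range(vol: Volume, params: GeodesicParams) -> IntensityRange:
    img = vol.channel(params.channel) if params.channel is not None else vol.reduced()
    return IntensityRange(float(img.min()), float(img.max()))


def cda2(
    s: Stroke,
    cam: Camera,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    region=None,
    smooth_window: Optional[int] = None,
    keep_dense: bool = False,
) -> Curve:
    """Chain geodesic shortest paths between consecutive rays (signal-seeking).

    The initial knot pair comes from one march between the voxel sets around
    the first two rays (both termini at once); every later knot is the first
    hit of a march from the previous knot to the voxels around the next ray.
    The finished knot chain is smoothed with a centered moving window.
    """
    if len(s) < 2:
        raise NoCurveError("curve generation needs a stroke of >= 2 points")
    live = _live_rays(s, cam, vol)
    irange = _metric_range(vol, params)
    if isinstance(region, SearchRegion):
        region = None if region.kind == "whole-overlap" else region.boxes
    sinks = [_ray_sink_voxels(r, vol.dims) for _, r in live]
    for (idx, _), sv in zip(live, sinks):
        if sv.shape[0] == 0:
            raise NoCurveError(f"no sink voxels around ray {idx}")
    def on_ray(voxel, ray):
        # the search visits voxels only; the resulting knot is corrected
        # locally to sub-voxel precision near the hit
        return _refine_knot(vol, params, voxel)

    try:
        path0 = fast_march(sinks[0], sinks[1], vol, params, region=region, irange=irange)
    except NoPathError as exc:
        raise NoCurveError(f"no geodesic path onto ray {live[1][0]}: {exc}") from exc
    anchors = [path0.voxels[0], path0.voxels[-1]]
    knots = [on_ray(path0.voxels[0], live[0][1]), on_ray(path0.voxels[-1], live[1][1])]
    cost = path0.cost
    visited = path0.visited
    dense = list(path0.voxels) if keep_dense else None
    for j in range(2, len(live)):
        try:
            leg = fast_march([anchors[-1]], sinks[j], vol, params, region=region, irange=irange)
        except NoPathError as exc:
            raise NoCurveError(f"no geodesic path onto ray {live[j][0]}: {exc}") from exc
        anchors.append(leg.voxels[-1])
        knots.append(on_ray(leg.voxels[-1], live[j][1]))
        cost += leg.cost
        visited += leg.visited
        if dense is not None:
            dense.extend(leg.voxels[1:])
    curve = Curve(
        np.array(knots, dtype=float),
        ray_index=[i for i, _ in live],
        dense_path=np.array(dense, dtype=float) if dense is not None else None,
        cost=cost,
        visited=visited,
    )
    if smooth_window is None:
        return Curve(_smooth_arc(curve.knots), ray_index=curve.ray_index,
                     dense_path=curve.dense_path, cost=curve.cost,
                     visited=curve.visited)
    return smooth_curve(curve, smooth_window)


def _refine_knot(vol: Volume, params: GeodesicParams, point, radius: int = 2,
                 iters: int = 2) -> np.ndarray:
    """Sub-voxel local correction of a knot: background-subtracted intensity
    centroid over a small voxel ball, iterated mean-shift style.

    Each knot is corrected locally toward the nearby intensity ridge so that
    stroke jitter and discretization do not accumulate along the curve; the
    correction is capped at ``radius`` voxels, so a knot cannot migrate to a
    different structure.
    """
    img = vol.channel(params.channel) if params.channel is not None else vol.reduced()
    dims = np.asarray(vol.dims, dtype=int)
    p = np.asarray(point, dtype=float).copy()
    start = p.copy()
    for _ in range(iters):
        c = np.round(p).astype(int)
        lo = np.maximum(c - radius, 0)
        hi = np.minimum(c + radius + 1, dims)
        block = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
        w = block - block.min()
        if w.sum() <= 0:
            break
        gx, gy, gz = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        new = np.array([(w * g).sum() for g in (gx, gy, gz)]) / w.sum()
        if np.linalg.norm(new - p) < 0.05:
            p = new
            break
        p = new
    step = p - start
    n = np.linalg.norm(step)
    if n > radius:
        p = start + step * (radius / n)
    return p


def _ray_candidates(ray: Ray, params: GeodesicParams, m: int, min_sep: float = 2.0):
    """Up to ``m`` brightest ray samples, mutually >= ``min_sep`` voxels apart.

    Brightness is ranked on a 3-sample moving average of the ray profile so a
    broad tube crossing outranks an isolated noise spike of similar height.
    Returns (continuous sample positions, rounded voxel coordinates).
    """
    inten = (
        ray.intensities[:, params.channel]
        if params.channel is not None
        else ray.intensities.max(axis=1)
    )
    if inten.shape[0] >= 3:
        from scipy.ndimage import uniform_filter1d

        inten = uniform_filter1d(inten.astype(float), size=3, mode="nearest")
    order = np.argsort(-inten, kind="stable")
    chosen: list[np.ndarray] = []
    seen: set[tuple[int, int, int]] = set()
    for i in order:
        p = ray.samples[i]
        v = tuple(np.round(p).astype(int))
        if v in seen:
            continue
        if all(np.linalg.norm(p - q) >= min_sep for q in chosen):
            chosen.append(p)
            seen.add(v)
            if len(chosen) >= m:
                break
    pos = np.array(chosen)
    idx = np.array([int(np.argmin(np.linalg.norm(ray.samples - p, axis=1))) for p in pos])
    return pos, np.round(pos).astype(int), idx


def cda2_global(
    s: Stroke,
    cam: Camera,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    m: int = 5,
    margin: int = 5,
    smooth_window: Optional[int] = None,
) -> Curve:
    """Globally optimal CDA2: minimum-total-cost chain over per-ray candidates.

    The stroke is preprocessed first (brightest 50% of points).  Each ray
    proposes up to ``m`` candidate points; exact pairwise geodesic costs
    between candidates of consecutive rays are computed with fast marching
    bounded to the margin-extended box around both candidate sets, and
    dynamic programming picks the cheapest chain from the first ray to the
    last.  ``m=1`` degenerates to greedy brightest-point chaining.
    """
    if len(s) < 2:
        raise NoCurveError("curve generation needs a stroke of >= 2 points")
    s = preprocess_stroke(s, cam, vol)
    live = _live_rays(s, cam, vol)
    irange = _metric_range(vol, params)
    cands = [_ray_candidates(r, params, m) for _, r in live]
    for (idx, _), cand in zip(live, cands):
        if cand[0].shape[0] == 0:
            raise NoCurveError(f"no candidate voxels on ray {idx}")
    dims = np.asarray(vol.dims, dtype=int)

    n_rays = len(live)
    best = [np.zeros(cands[0][0].shape[0])]
    back: list[np.ndarray] = []
    for k in range(1, n_rays):
        a_vox, b_vox = cands[k - 1][1], cands[k][1]
        both = np.vstack([a_vox, b_vox])
        lo = np.clip(both.min(axis=0) - margin, 0, dims)
        hi = np.clip(both.max(axis=0) + 1 + margin, 0, dims)
        box = [(lo, hi)]
        legs = np.full((a_vox.shape[0], b_vox.shape[0]), np.inf)
        for i, a in enumerate(a_vox):
            legs[i] = geodesic_costs([a], b_vox, vol, params, region=box, irange=irange)
        tot = best[-1][:, None] + legs
        if not np.any(np.isfinite(tot)):
            raise NoCurveError(f"no geodesic path onto ray {live[k][0]} within candidate boxes")
        back.append(np.argmin(tot, axis=0))
        best.append(tot.min(axis=0))
    j = int(np.argmin(best[-1]))
    total_cost = float(best[-1][j])
    chain = [j]
    for k in range(n_rays - 1, 0, -1):
        chain.append(int(back[k - 1][chain[-1]]))
    chain.reverse()
    chain_pts = [_refine_knot(vol, params, cands[k][0][c]) for k, c in enumerate(chain)]
    # The winning chain is a minimum-cost *path*: when consecutive chain
    # points are far apart (preprocessing dropped a run of stroke points),
    # the dense geodesic leg is carried into the curve so it follows the
    # signal rather than the straight chord.
    leg_len = [np.linalg.norm(b - a) for a, b in zip(chain_pts[:-1], chain_pts[1:])]
    bridge_at = 2.5 * float(np.median(leg_len)) if leg_len else np.inf
    knots = [chain_pts[0]]
    for k in range(1, n_rays):
        if leg_len[k - 1] > max(bridge_at, 4.0):
            a_vox = cands[k - 1][1][chain[k - 1]]
            b_vox = cands[k][1][chain[k]]
            both = np.vstack([a_vox, b_vox])
            lo = np.clip(both.min(axis=0) - margin, 0, dims)
            hi = np.clip(both.max(axis=0) + 1 + margin, 0, dims)
            try:
                leg = fast_march([a_vox], [b_vox], vol, params,
                                 region=[(lo, hi)], irange=irange)
                mid = np.asarray(leg.voxels[1:-1], dtype=float)
                if mid.shape[0] > 2:
                    mid = resample_polyline(mid, 3.0)
                for p in mid:
                    knots.append(_refine_knot(vol, params, p))
            except NoPathError:
                pass
        knots.append(chain_pts[k])
    knots = np.array(knots, dtype=float)
    ray_index = [i for i, _ in live] if knots.shape[0] == n_rays else None
    curve = Curve(knots, ray_index=ray_index, cost=total_cost)
    if smooth_window is None:
        return Curve(_smooth_arc(curve.knots), ray_index=curve.ray_index,
                     dense_path=curve.dense_path, cost=curve.cost,
                     visited=curve.visited)
    return smooth_curve(curve, smooth_window)


def cda2_bbox(
    s: Stroke,
    cam: Camera,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    margin: int = 5,
    smooth_window: Optional[int] = None,
) -> Curve:
    """CDA2 restricted to margin-extended boxes around preliminary pinpoints.

    Preliminary per-ray pinpoints define consecutive-pair bounding boxes,
    expanded by ``margin`` (default 5 voxels); the marches of CDA2 only visit
    the union of those boxes.  A too-small margin on a curved structure can
    disconnect the region, in which case the no-curve error propagates rather
    than returning a wrong curve (callers may enlarge the margin).
    """
    if len(s) < 2:
        raise NoCurveError("curve generation needs a stroke of >= 2 points")
    live = _live_rays(s, cam, vol)
    dims = np.asarray(vol.dims, dtype=int)
    hits = []
    for _, ray in live:
        gi, _, _ = _ppa_on_ray(ray)
        hits.append(ray.samples[gi])
    boxes = []
    for a, b in zip(hits[:-1], hits[1:]):
        pair = np.vstack([a, b])
        lo = np.clip(np.floor(pair.min(axis=0)).astype(int) - margin, 0, dims)
        hi = np.clip(np.ceil(pair.max(axis=0)).astype(int) + 1 + margin, 0, dims)
        boxes.append((lo, hi))
    return cda2(s, cam, vol, params, region=boxes, smooth_window=smooth_window)


# ---------------------------------------------------------------------------
# Curve utilities


def _smooth_arc(knots: np.ndarray, arc_voxels: float = 5.0) -> np.ndarray:
    """Moving-window smoothing measured in voxels of arc length.

    Each interior knot is replaced by the mean of the (finely resampled)
    knot polyline within ``arc_voxels/2`` of arc on either side of it, so
    the window has a fixed physical width regardless of how densely the
    stroke sampled the curve; endpoints stay fixed.  Collinear evenly
    spaced knots are a fixed point.
    """
    k = np.atleast_2d(knots)
    n = k.shape[0]
    if n < 3:
        return k.copy()
    seg = np.linalg.norm(np.diff(k, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        return k.copy()
    step = 0.25
    fine_t = np.arange(0.0, arc[-1] + step / 2, step)
    fine = np.stack([np.interp(fine_t, arc, k[:, a]) for a in range(3)], axis=1)
    out = k.copy()
    half = arc_voxels / 2.0
    for i in range(1, n - 1):
        # symmetric window, shrunk near the ends so the mean stays centered
        h = min(half, arc[i], arc[-1] - arc[i])
        sel = np.abs(fine_t - arc[i]) <= h + 1e-9
        if np.any(sel):
            out[i] = fine[sel].mean(axis=0)
    return out


def smooth_curve(c: Curve, window: int = 5) -> Curve:
    """Centered moving average over knots; endpoints stay fixed.

    Near the ends the window shrinks symmetrically, so collinear, evenly
    spaced knots are a fixed point of the operation.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    k = c.knots
    n = k.shape[0]
    half = window // 2
    out = k.copy()
    for i in range(1, n - 1):
        h = min(half, i, n - 1 - i)
        out[i] = k[i - h : i + h + 1].mean(axis=0)
    return Curve(out, ray_index=c.ray_index, dense_path=c.dense_path,
                 cost=c.cost, visited=c.visited)


def spatial_divergence(a: Curve, b: Curve) -> dict:
    """Symmetric spatial-divergence score between two curves.

    Both curves are resampled at one-voxel arc length; the directed mean
    nearest-point distance is computed in both directions and averaged.
    Returns ``{"mean", "max", "fraction_visible"}`` where *visible* means a
    sample at least 2 voxels from the other curve.
    """
    ka, kb = np.atleast_2d(a.knots), np.atleast_2d(b.knots)
    if ka.shape[0] < 2 or kb.shape[0] < 2:
        raise MetricError("spatial divergence needs curves with >= 2 knots")
    ra, rb = resample_polyline(ka), resample_polyline(kb)
    if ra.shape[0] < 2 or rb.shape[0] < 2:
        raise MetricError("cannot resample a zero-length curve")
    d_ab = _point_to_segments(ra, rb)
    d_ba = _point_to_segments(rb, ra)
    pooled = np.concatenate([d_ab, d_ba])
    return {
        "mean": float(0.5 * (d_ab.mean() + d_ba.mean())),
        "max": float(pooled.max()),
        "fraction_visible": float((pooled >= 2.0).mean()),
    }


def similarity_transform(scale: float = 1.0, rotation=None, translation=(0, 0, 0)) -> np.ndarray:
    """4x4 similarity transform (uniform zoom, rotation, shift)."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    M = np.eye(4)
    M[:3, :3] = scale * R
    M[:3, 3] = np.asarray(translation, dtype=float)
    return M


def mirror_transform(axis: int, center: float = 0.0) -> np.ndarray:
    """4x4 mirror about the plane ``coordinate[axis] == center``."""
    M = np.eye(4)
    M[axis, axis] = -1.0
    M[axis, 3] = 2.0 * center
    return M


def transform_curve(c: Curve, t) -> Curve:
    """Apply a rigid/similarity/mirror transform (4x4 matrix) to every knot."""
    M = np.asarray(t, dtype=float)
    if M.shape == (3, 3):
        A = similarity_transform(rotation=M)
    elif M.shape == (4, 4):
        A = M
    else:
        raise ValueError("transform must be a 3x3 or 4x4 matrix")
    hom = np.concatenate([c.knots, np.ones((len(c), 1))], axis=1)
    return Curve((hom @ A.T)[:, :3], ray_index=c.ray_index)


def drag_knot(c: Curve, knot: int, delta, radius: int = 0) -> Curve:
    """Drag one knot; neighbors within ``radius`` indices follow with a
    cosine falloff so the curve deforms smoothly."""
    if not 0 <= knot < len(c):
        raise IndexError(f"knot {knot} out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    delta = np.asarray(delta, dtype=float)
    out = c.knots.copy()
    for i in range(max(0, knot - radius), min(len(c), knot + radius + 1)):
        d = abs(i - knot)
        w = 0.5 * (1.0 + math.cos(math.pi * d / (radius + 1)))
        out[i] = out[i] + w * delta
    return Curve(out, ray_index=c.ray_index)


def connected_components(curves: Sequence[Curve], tol: float = 1e-6) -> int:
    """Number of connected components, where curves sharing a knot (within
    ``tol``) are connected."""
    n = len(curves)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = curves[i].knots, curves[j].knots
            d = np.linalg.norm(ki[:, None, :] - kj[None, :, :], axis=2)
            if d.min() <= tol:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def join_segments(segments: Sequence[Curve], threshold: float = 5.0) -> list[Curve]:
    """Auto-join curve segments whose endpoints come close to other segments.

    Whenever an endpoint of one segment lies within ``threshold`` voxels
    (inclusive, default 5) of any point of another segment, the junction
    point is inserted into both so they share it exactly; existing knots are
    never moved.  Repeats until no more joins are possible.  The returned
    segments form connected structures through their shared junction knots
    (see :func:`connected_components`).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    curves = [Curve(c.knots.copy(), ray_index=None) for c in segments]
    n = len(curves)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    changed = True
    while changed:
        changed = False
        for i in range(n):
            for end in (0, -1):
                e = curves[i].knots[end]
                best = None
                for j in range(n):
                    if j == i or find(i) == find(j):
                        continue
                    d, q, ins = _nearest_on_polyline(e, curves[j].knots)
                    if d <= threshold and (best is None or d < best[0]):
                        best = (d, q, ins, j)
                if best is None:
                    continue
                d, q, ins, j = best
                kj = curves[j].knots
                if not np.any(np.linalg.norm(kj - q, axis=1) <= 1e-9):
                    curves[j] = Curve(np.insert(kj, ins, q, axis=0))
                ki = curves[i].knots
                if np.linalg.norm(e - q) > 1e-9:
                    if end == 0:
                        curves[i] = Curve(np.vstack([q, ki]))
                    else:
                        curves[i] = Curve(np.vstack([ki, q]))
                parent[find(i)] = find(j)
                changed = True
    return curves


# ---------------------------------------------------------------------------
# SWC I/O (one curve = a chain of nodes linked by parent pointers)


def write_swc(curves, path, radius: float = 1.0, node_type: int = 3) -> None:
    if isinstance(curves, Curve):
        curves = [curves]
    lines = ["# generated by vfinger", "# id type x y z radius parent"]
    nid = 0
    for c in curves:
        for i, (x, y, z) in enumerate(c.knots):
            nid += 1
            parent = -1 if i == 0 else nid - 1
            lines.append(f"{nid} {node_type} {x:.6g} {y:.6g} {z:.6g} {radius:.6g} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> list[Curve]:
    nodes: dict[int, tuple[np.ndarray, int]] = {}
    order: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        nid, parent = int(parts[0]), int(parts[6])
        nodes[nid] = (np.array([float(parts[2]), float(parts[3]), float(parts[4])]), parent)
        order.append(nid)
    children: dict[int, list[int]] = {}
    for nid in order:
        p = nodes[nid][1]
        children.setdefault(p, []).append(nid)
    curves = []
    # start a chain at every root and at every branch child
    starts = []
    for nid in order:
        p = nodes[nid][1]
        if p == -1 or p not in nodes or len(children.get(p, [])) > 1:
            starts.append(nid)
    for s in starts:
        chain = []
        p = nodes[s][1]
        if p in nodes:
            chain.append(nodes[p][0])  # include the branch point
        cur = s
        while True:
            chain.append(nodes[cur][0])
            kids = children.get(cur, [])
            if len(kids) != 1:
                break
            cur = kids[0]
        if len(chain) >= 1:
            curves.append(Curve(np.array(chain)))
    return curves
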