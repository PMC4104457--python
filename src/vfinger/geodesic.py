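"""Intensity-weighted voxel-graph metric and a fast-marching shortest-path engine.

The volume is treated as an implicit graph: every voxel is a node, spatially
adjacent voxels (6-, 18- or 26-connected; default 18) share an edge, and the
edge weight between adjacent voxels ``u`` and ``v`` is::

    w(u, v) = ||u - v|| * (g_I(I(u)) + g_I(I(v))) / 2
    g_I(i)  = exp(lambda_I * (1 - (i - I_min) / (I_max - I_min))**2)

so bright voxels are cheap to traverse and dark voxels exponentially
expensive (``lambda_I`` defaults to 10).  ``fast_march`` propagates a
best-first wavefront from a set of source voxels until it finalizes a sink
voxel — the "first hit-point" — without ever materializing the graph.  The
propagation is cost-correct (equivalent to Dijkstra on the explicit graph);
ties on the frontier are broken by the lowest (z, y, x) voxel so results are
deterministic across platforms.

The inner loop is compiled with numba when available and falls back to a
pure-Python heap otherwise.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NoPathError
from .volume import IntensityRange, Volume

__all__ = [
    "GeodesicParams",
    "GeodesicPath",
    "g_intensity",
    "edge_weight",
    "fast_march",
    "geodesic_costs",
    "neighbor_offsets",
]


@dataclass(frozen=True)
class GeodesicParams:
    """Tunables of the geodesic metric.

    lambda_i : weighting factor of the intensity penalty (default 10).
    connectivity : 6 (faces), 18 (faces+edges, default) or 26 (+corners).
    channel : which channel drives the metric; None = per-voxel max across
        channels (what a MIP viewer shows).
    """

    lambda_i: float = 10.0
    connectivity: int = 18
    channel: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda_i < 0:
            raise ValueError("lambda_i must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class GeodesicPath:
    """An ordered chain of adjacent voxels with its accumulated cost."""

    voxels: list[tuple[int, int, int]]
    cost: float
    visited: int = 0  # voxels finalized by the search (instrumentation)


def neighbor_offsets(connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    """(K, 3) integer offsets and their Euclidean step lengths."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                m = abs(dx) + abs(dy) + abs(dz)
                if m == 0:
                    continue
                if connectivity == 6 and m > 1:
                    continue
                if connectivity == 18 and m > 2:
                    continue
                offs.append((dx, dy, dz))
    offs = np.array(offs, dtype=np.int64)
    return offs, np.sqrt((offs**2).sum(axis=1)).astype(np.float64)


def g_intensity(i, r: IntensityRange, params: GeodesicParams = GeodesicParams()):
    """Intensity penalty ``exp(lambda * (1 - norm(i))**2)``; 1.0 at i = i_max.

    On a flat image (i_min == i_max) the normalized intensity is taken as 1,
    so the penalty degenerates to 1 and the metric becomes Euclidean.
    """
    i = np.asarray(i, dtype=float)
    if r.span == 0:
        norm = np.ones_like(i)
    else:
        norm = (i - r.i_min) / r.span
    out = np.exp(params.lambda_i * (1.0 - norm) ** 2)
    return float(out) if out.ndim == 0 else out


def _metric_image(vol: Volume, params: GeodesicParams) -> np.ndarray:
    if params.channel is not None:
        return vol.channel(params.channel).astype(float)
    return vol.reduced().astype(float)


def edge_weight(u, v, vol: Volume, params: GeodesicParams = GeodesicParams()) -> float:
    """Euclidean distance between adjacent voxels times the mean g_I penalty."""
    u = np.asarray(u, dtype=int)
    v = np.asarray(v, dtype=int)
    d = np.abs(u - v)
    m = int(d.sum())
    if np.any(d > 1) or m == 0 or (params.connectivity == 6 and m > 1) or (
        params.connectivity == 18 and m > 2
    ):
        raise ValueError(f"{tuple(u)} and {tuple(v)} are not "
                         f"{params.connectivity}-connected neighbors")
    img = _metric_image(vol, params)
    r = IntensityRange(float(img.min()), float(img.max()))
    gu = g_intensity(img[tuple(u)], r, params)
    gv = g_intensity(img[tuple(v)], r, params)
    return float(np.linalg.norm(u - v) * 0.5 * (gu + gv))


# ---------------------------------------------------------------------------
# Search kernel.  Operates on a flattened sub-box with C-order (x, y, z) flat
# indices; the tie-break key orders voxels by (z, y, x).


def _march_py(g, mask, sink, sources, offs, steps, nx, ny, nz, stop_after):
    n = nx * ny * nz
    dist = np.full(n, np.inf)
    parent = np.full(n, -1, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    heap = []
    for s in sources:
        if mask[s] and dist[s] > 0.0:
            dist[s] = 0.0
            x, r = divmod(s, ny * nz)
            y, z = divmod(r, nz)
            heapq.heappush(heap, (0.0, (z * ny + y) * nx + x, s))
    hit = np.int64(-1)
    visited = 0
    nfound = 0
    while heap:
        d, _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        visited += 1
        if sink[u]:
            if hit < 0:
                hit = u
            nfound += 1
            if nfound >= stop_after:
                break
        x, r = divmod(u, ny * nz)
        y, z = divmod(r, nz)
        for o in range(offs.shape[0]):
            xx = x + offs[o, 0]
            yy = y + offs[o, 1]
            zz = z + offs[o, 2]
            if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                continue
            v = (xx * ny + yy) * nz + zz
            if done[v] or not mask[v]:
                continue
            nd = d + steps[o] * 0.5 * (g[u] + g[v])
            if nd < dist[v]:
                dist[v] = nd
                parent[v] = u
                heapq.heappush(heap, (nd, (zz * ny + yy) * nx + xx, v))
    return dist, parent, hit, visited


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    @numba.njit(cache=True)
    def _march_nb(g, mask, sink, sources, offs, steps, nx, ny, nz, stop_after):
        n = nx * ny * nz
        dist = np.full(n, np.inf)
        parent = np.full(n, -1, dtype=np.int64)
        done = np.zeros(n, dtype=numba.boolean)
        cap = 1024
        hd = np.empty(cap)
        hk = np.empty(cap, dtype=np.int64)
        hn = np.empty(cap, dtype=np.int64)
        size = 0
        for si in range(sources.shape[0]):
            s = sources[si]
            if mask[s] and dist[s] > 0.0:
                dist[s] = 0.0
                x = s // (ny * nz)
                r = s % (ny * nz)
                y = r // nz
                z = r % nz
                k = (z * ny + y) * nx + x
                # push
                if size == cap:
                    cap *= 2
                    hd2 = np.empty(cap)
                    hk2 = np.empty(cap, dtype=np.int64)
                    hn2 = np.empty(cap, dtype=np.int64)
                    hd2[:size] = hd[:size]
                    hk2[:size] = hk[:size]
                    hn2[:size] = hn[:size]
                    hd, hk, hn = hd2, hk2, hn2
                hd[size] = 0.0
                hk[size] = k
                hn[size] = s
                i = size
                size += 1
                while i > 0:
                    p = (i - 1) // 2
                    if hd[p] > hd[i] or (hd[p] == hd[i] and hk[p] > hk[i]):
                        hd[p], hd[i] = hd[i], hd[p]
                        hk[p], hk[i] = hk[i], hk[p]
                        hn[p], hn[i] = hn[i], hn[p]
                        i = p
                    else:
                        break
        hit = np.int64(-1)
        visited = 0
        nfound = 0
        while size > 0:
            d = hd[0]
            u = hn[0]
            size -= 1
            hd[0] = hd[size]
            hk[0] = hk[size]
            hn[0] = hn[size]
            i = 0
            while True:
                l = 2 * i + 1
                rgt = l + 1
                m = i
                if l < size and (hd[l] < hd[m] or (hd[l] == hd[m] and hk[l] < hk[m])):
                    m = l
                if rgt < size and (hd[rgt] < hd[m] or (hd[rgt] == hd[m] and hk[rgt] < hk[m])):
                    m = rgt
                if m == i:
                    break
                hd[m], hd[i] = hd[i], hd[m]
                hk[m], hk[i] = hk[i], hk[m]
                hn[m], hn[i] = hn[i], hn[m]
                i = m
            if done[u]:
                continue
            done[u] = True
            visited += 1
            if sink[u]:
                if hit < 0:
                    hit = u
                nfound += 1
                if nfound >= stop_after:
                    break
            x = u // (ny * nz)
            r = u % (ny * nz)
            y = r // nz
            z = r % nz
            for o in range(offs.shape[0]):
                xx = x + offs[o, 0]
                yy = y + offs[o, 1]
                zz = z + offs[o, 2]
                if xx < 0 or xx >= nx or yy < 0 or yy >= ny or zz < 0 or zz >= nz:
                    continue
                v = (xx * ny + yy) * nz + zz
                if done[v] or not mask[v]:
                    continue
                nd = d + steps[o] * 0.5 * (g[u] + g[v])
                if nd < dist[v]:
                    dist[v] = nd
                    parent[v] = u
                    k = (zz * ny + yy) * nx + xx
                    if size == cap:
                        cap *= 2
                        hd2 = np.empty(cap)
                        hk2 = np.empty(cap, dtype=np.int64)
                        hn2 = np.empty(cap, dtype=np.int64)
                        hd2[:size] = hd[:size]
                        hk2[:size] = hk[:size]
                        hn2[:size] = hn[:size]
                        hd, hk, hn = hd2, hk2, hn2
                    hd[size] = nd
                    hk[size] = k
                    hn[size] = v
                    i = size
                    size += 1
                    while i > 0:
                        p = (i - 1) // 2
                        if hd[p] > hd[i] or (hd[p] == hd[i] and hk[p] > hk[i]):
                            hd[p], hd[i] = hd[i], hd[p]
                            hk[p], hk[i] = hk[i], hk[p]
                            hn[p], hn[i] = hn[i], hn[p]
                            i = p
                        else:
                            break
        return dist, parent, hit, visited

    _march = _march_nb
except Exception:  # pragma: no cover
    _march = _march_py


# ---------------------------------------------------------------------------
# Region handling


def _region_to_box_mask(region, dims):
    """Normalize a region (None | bool array | box | box list) to a sub-box
    ``(lo, hi)`` (half-open, int arrays) plus a boolean mask over that box."""
    dims = np.asarray(dims, dtype=int)
    if region is None:
        lo = np.zeros(3, dtype=int)
        hi = dims.copy()
        return lo, hi, np.ones(tuple(hi - lo), dtype=bool)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != tuple(dims):
            raise ValueError("region mask shape must match volume dims")
        idx = np.argwhere(region)
        if idx.size == 0:
            raise ValueError("region mask is empty")
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        return lo, hi, region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    # a single box or an iterable of boxes, each with min_corner/max_corner
    boxes = region if isinstance(region, (list, tuple)) else [region]
    corners = []
    for b in boxes:
        mn = np.asarray(getattr(b, "min_corner", b[0]), dtype=int)
        mx = np.asarray(getattr(b, "max_corner", b[1]), dtype=int)
        mn = np.clip(mn, 0, dims)
        mx = np.clip(mx, 0, dims)
        corners.append((mn, mx))
    lo = np.minimum.reduce([c[0] for c in corners])
    hi = np.maximum.reduce([c[1] for c in corners])
    if np.any(hi <= lo):
        raise ValueError("region boxes are empty after clipping")
    mask = np.zeros(tuple(hi - lo), dtype=bool)
    for mn, mx in corners:
        mask[mn[0]-lo[0]:mx[0]-lo[0], mn[1]-lo[1]:mx[1]-lo[1], mn[2]-lo[2]:mx[2]-lo[2]] = True
    return lo, hi, mask


def _prep(vol, params, region, sources, sinks, irange):
    img = _metric_image(vol, params)
    if irange is None:
        irange = IntensityRange(float(img.min()), float(img.max()))
    lo, hi, mask = _region_to_box_mask(region, vol.dims)
    shape = tuple(hi - lo)
    sub = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    g = np.ascontiguousarray(g_intensity(sub, irange, params), dtype=np.float64)

    def to_flat(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=int))
        rel = pts - lo
        ok = np.all((rel >= 0) & (rel < shape), axis=1)
        rel = rel[ok]
        if rel.shape[0]:
            flat = (rel[:, 0] * shape[1] + rel[:, 1]) * shape[2] + rel[:, 2]
            flat = flat[mask.ravel()[flat]]
        else:
            flat = np.empty(0, dtype=np.int64)
        return flat.astype(np.int64)

    src = to_flat(sources)
    snk = to_flat(sinks)
    if src.size == 0:
        raise ValueError("no source voxel lies inside the search region")
    if snk.size == 0:
        raise ValueError("no sink voxel lies inside the search region")
    sink_flat = np.zeros(int(np.prod(shape)), dtype=bool)
    sink_flat[snk] = True
    offs, steps = neighbor_offsets(params.connectivity)
    return g, mask, sink_flat, src, snk, offs, steps, lo, shape


def _unflatten(flat, lo, shape):
    x, r = divmod(int(flat), shape[1] * shape[2])
    y, z = divmod(r, shape[2])
    return (x + int(lo[0]), y + int(lo[1]), z + int(lo[2]))


def _walk_back(parent, hit, lo, shape):
    chain = []
    u = int(hit)
    while u >= 0:
        chain.append(_unflatten(u, lo, shape))
        u = int(parent[u])
    chain.reverse()
    return chain


def fast_march(
    sources,
    sinks,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    region=None,
    irange: Optional[IntensityRange] = None,
) -> GeodesicPath:
    """Minimum-cost path from any source to the first-reached sink.

    ``sources`` and ``sinks`` are (N, 3) integer voxel coordinates (a single
    triple is accepted).  ``region`` optionally confines the search: a boolean
    mask over the volume, a box with ``min_corner``/``max_corner`` (half-open),
    or a list of such boxes.  Raises :class:`NoPathError` when every sink is
    unreachable within the region.
    """
    g, mask, sink_flat, src, snk, offs, steps, lo, shape = _prep(
        vol, params, region, sources, sinks, irange
    )
    dist, parent, hit, visited = _march(
        g.ravel(), mask.ravel(), sink_flat, src, offs, steps,
        shape[0], shape[1], shape[2], 1,
    )
    if hit < 0:
        raise NoPathError(
            f"no path: {len(snk)} sink voxel(s) unreachable from "
            f"{len(src)} source voxel(s) within the search region"
        )
    return GeodesicPath(_walk_back(parent, hit, lo, shape), float(dist[hit]), int(visited))


def geodesic_costs(
    sources,
    sinks,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    region=None,
    irange: Optional[IntensityRange] = None,
) -> np.ndarray:
    """Geodesic cost from the source set to *each* sink (inf if unreachable).

    Used by the globally optimal curve variant, which needs all pairwise leg
    costs rather than just the first hit.
    """
    sinks = np.atleast_2d(np.asarray(sinks, dtype=int))
    g, mask, sink_flat, src, snk, offs, steps, lo, shape = _prep(
        vol, params, region, sources, sinks, irange
    )
    dist, parent, hit, visited = _march(
        g.ravel(), mask.ravel(), sink_flat, src, offs, steps,
        shape[0], shape[1], shape[2], int(snk.size),
    )
    out = np.full(sinks.shape[0], np.inf)
    for i, p in enumerate(sinks):
        rel = p - lo
        if np.all((rel >= 0) & (rel < shape)):
            flat = (rel[0] * shape[1] + rel[1]) * shape[2] + rel[2]
            out[i] = dist[flat]
    return out
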