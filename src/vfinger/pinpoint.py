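"""One-click 3D point generation (point-pinpointing algorithms).

``ppa_single`` localizes the dominant intensity peak along one shooting ray
with a progressive mean-shift: the search range starts as the whole sampled
segment, is recentered on the intensity-weighted centroid and halved each
iteration, and stops once the centroid moves less than half a voxel or the
range covers at most three samples.  ``ppa_c`` runs this per color channel
and keeps the candidate with the brightest raw voxel intensity; ``ppa_n``
trades the click for a micro-stroke and delegates to the noise-robust curve
engine, returning the first curve knot.

Returned locations are snapped to the ray's one-voxel sample grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NoPointError
from .geodesic import GeodesicParams
from .projection import Camera, Ray, Stroke, screen_to_ray
from .volume import Volume, intensity_range

__all__ = ["PinpointResult", "ppa_single", "ppa_c", "ppa_n", "write_markers", "read_markers"]


@dataclass
class PinpointResult:
    location: np.ndarray  # 3D, continuous
    channel: int
    intensity: float
    confident: bool = True


def _mean_shift_peak(positions: np.ndarray, weights: np.ndarray) -> tuple[int, bool]:
    """Progressive mean-shift on a 1D intensity profile.

    ``positions`` are scalar arc-length coordinates of the samples (spacing
    1.0), ``weights`` their intensities.  Returns (index of the winning
    sample, confident flag).
    """
    n = positions.shape[0]
    if n == 0:
        raise NoPointError("ray has no in-volume samples")
    if np.all(weights == weights[0]):
        # flat profile: no peak to converge to; take the middle sample
        return n // 2, False
    lo, hi = positions[0], positions[-1]
    center = 0.5 * (lo + hi)
    for _ in range(64):
        half = 0.5 * (hi - lo)
        inside = (positions >= lo) & (positions <= hi)
        w = weights[inside].astype(float)
        pos = positions[inside]
        if pos.size == 0:
            break
        # subtract the in-range floor so a broad background pedestal does
        # not drag the centroid toward the middle of the ray
        w = w - w.min()
        if w.sum() <= 0:
            break
        new_center = float((w * pos).sum() / w.sum())
        moved = abs(new_center - center)
        center = new_center
        half *= 0.5
        lo, hi = center - half, center + half
        if moved < 0.5 or inside.sum() <= 3:
            break
    inside = (positions >= lo) & (positions <= hi)
    if not np.any(inside):
        inside = np.abs(positions - center) == np.abs(positions - center).min()
    idx = np.flatnonzero(inside)
    w = weights[idx]
    best = idx[w == w.max()]
    if best.size > 1:  # tie: nearest the centroid
        best = best[np.argmin(np.abs(positions[best] - center))]
    else:
        best = best[0]
    return int(best), True


def ppa_single(ray: Ray, channel: int = 0) -> PinpointResult:
    """Pinpoint along one ray in one channel via progressive mean-shift."""
    if ray.is_empty:
        raise NoPointError("ray misses the volume")
    weights = ray.intensities[:, channel]
    positions = np.arange(weights.shape[0], dtype=float)  # samples 1 voxel apart
    idx, confident = _mean_shift_peak(positions, weights)
    return PinpointResult(
        location=ray.samples[idx].copy(),
        channel=channel,
        intensity=float(weights[idx]),
        confident=confident,
    )


def ppa_c(
    strokepoint,
    cam: Camera,
    vol: Volume,
    channel: Optional[int] = None,
    normalized: bool = False,
) -> PinpointResult:
    """Multi-channel pinpoint: per-channel candidates, brightest raw intensity wins.

    ``channel`` fixes a particular color channel instead of competing them all.
    ``normalized`` compares candidates on per-channel normalized intensity
    (useful when dynamic ranges differ wildly); the default compares raw
    values.  Ties go to the lowest channel index.
    """
    ray = screen_to_ray(strokepoint, cam, vol)
    if ray.is_empty:
        raise NoPointError(f"ray through screen point {tuple(strokepoint)} misses the volume")
    if channel is not None:
        return ppa_single(ray, channel)
    best: Optional[PinpointResult] = None
    best_score = -np.inf
    for c in range(vol.n_channels):
        cand = ppa_single(ray, c)
        score = cand.intensity
        if normalized:
            r = intensity_range(vol, c)
            score = (score - r.i_min) / r.span if r.span else 1.0
        if score > best_score:  # strict: ties keep the lowest channel
            best, best_score = cand, score
    assert best is not None
    return best


def ppa_n(
    short_stroke: Stroke,
    cam: Camera,
    vol: Volume,
    params: GeodesicParams = GeodesicParams(),
    presmooth_sigma: float = 1.0,
    min_sep_px: float = 3.0,
) -> PinpointResult:
    """Noise-robust pinpoint from a very short stroke around the click.

    The micro-stroke is run through the curve engine (CDA2) and the first
    curve knot — the point on the ray of the stroke's starting location — is
    returned; a single-point stroke falls back to :func:`ppa_c`.

    Two measures make the estimate robust on heavily contaminated images:
    cursor samples closer than ``min_sep_px`` screen pixels are collapsed
    (near-duplicate rays make the source and sink voxel sets of the first
    march overlap, which degenerates the geodesic), and the geodesic runs on
    a copy of the volume presmoothed with a Gaussian of ``presmooth_sigma``
    voxels, so coherent 3D structure outweighs single-voxel noise spikes.
    Set ``presmooth_sigma=0`` to run on the raw intensities, which makes the
    result exactly the first knot of the plain curve algorithm.
    """
    pts = short_stroke.points
    keep = [pts[0]]
    for p in pts[1:]:
        if np.linalg.norm(p - keep[-1]) >= min_sep_px:
            keep.append(p)
    if len(keep) < 2 and np.linalg.norm(pts[-1] - keep[-1]) >= 1.0:
        keep.append(pts[-1])
    if len(keep) < 2:
        return ppa_c(pts[0], cam, vol)
    from .curve import cda2  # local import: curve depends on pinpoint

    work = vol
    if presmooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        sm = np.stack(
            [gaussian_filter(vol.channel(c).astype(float), presmooth_sigma)
             for c in range(vol.n_channels)],
            axis=-1,
        )
        work = Volume(sm, voxel_size=vol.voxel_size)
    c = cda2(Stroke(np.array(keep)), cam, work, params)
    loc = np.asarray(c.knots[0], dtype=float)
    img = vol.reduced() if params.channel is None else vol.channel(params.channel)
    vox = tuple(np.clip(np.round(loc).astype(int), 0, np.asarray(vol.dims) - 1))
    return PinpointResult(
        location=loc,
        channel=params.channel if params.channel is not None else 0,
        intensity=float(img[vox]),
        confident=True,
    )


# ---------------------------------------------------------------------------
# Marker table I/O (Vaa3D-compatible CSV: 1-based coordinates on disk,
# 0-based in memory).

_MARKER_HEADER = ["x", "y", "z", "radius", "channel", "name"]


def write_markers(results, path, names=None, radius: float = 1.0) -> None:
    results = list(results)
    names = list(names) if names is not None else [f"m{i+1}" for i in range(len(results))]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MARKER_HEADER)
        for res, name in zip(results, names):
            x, y, z = (float(v) + 1.0 for v in res.location)  # 1-based on export
            w.writerow([x, y, z, radius, res.channel, name])


def read_markers(path) -> list[PinpointResult]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            loc = np.array([float(row["x"]), float(row["y"]), float(row["z"])]) - 1.0
            out.append(PinpointResult(loc, int(row.get("channel", 0) or 0), np.nan))
    return out
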