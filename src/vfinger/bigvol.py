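"""Multi-resolution octree pyramid for volumes too large to load whole.

The builder iteratively downsamples a stack by 2 along each of X, Y and Z
(2x2x2 block mean; edge blocks average the voxels that exist) until a preset
leaf cap (default 512x512x256) is reached.  Every level is stored tile-wise
as plain TIFF files in one directory per level, linked by a JSON index, so a
region of interest at any displayed resolution can be mapped to the minimal
tile set at any other resolution and loaded without touching the rest of the
volume — the work depends only on the ROI size, never on the total stack
size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import IntegrityError
from .volume import Volume, read_volume, write_volume

__all__ = ["OctreeIndex", "ResolvedRoi", "build_octree", "resolve_roi", "load_block"]

DEFAULT_LEAF_CAP = (512, 512, 256)
DEFAULT_TILE_SIZE = (256, 256, 256)


@dataclass
class ResolvedRoi:
    level: int
    box: tuple  # (lo, hi) half-open at the target level
    tiles: list  # tile metadata dicts covering the box
    tiles_examined: int  # grid cells inspected; independent of volume size


@dataclass
class OctreeIndex:
    """Descriptor of the stored pyramid; ``levels[0]`` is the coarsest."""

    root: Path
    levels: list  # [{dims, tile_size, tiles: [{offset, shape, path}]}]
    dtype: str
    channels: int
    leaf_cap: tuple = DEFAULT_LEAF_CAP

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        for k in range(len(self.levels) - 1):
            coarse = self.levels[k]["dims"]
            fine = self.levels[k + 1]["dims"]
            if any(c != (f + 1) // 2 for c, f in zip(coarse, fine)):
                raise IntegrityError(
                    f"level {k} dims {coarse} are not the ceil-half of level {k+1} {fine}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def tile_lookup(self, level: int) -> dict:
        """Map grid offset -> tile metadata for one level (built lazily)."""
        cache = getattr(self, "_lookup", None)
        if cache is None:
            cache = {}
            self._lookup = cache
        if level not in cache:
            cache[level] = {tuple(t["offset"]): t for t in self.levels[level]["tiles"]}
        return cache[level]

    def save(self) -> None:
        doc = {
            "dtype": self.dtype,
            "channels": self.channels,
            "leaf_cap": list(self.leaf_cap),
            "levels": self.levels,
        }
        (self.root / "index.json").write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, root) -> "OctreeIndex":
        root = Path(root)
        path = root / "index.json"
        if not path.exists():
            raise IntegrityError(f"{path}: octree index not found")
        doc = json.loads(path.read_text())
        return cls(root, doc["levels"], doc["dtype"], doc["channels"],
                   tuple(doc.get("leaf_cap", DEFAULT_LEAF_CAP)))


def plan_levels(dims, leaf_cap=DEFAULT_LEAF_CAP) -> list[tuple[int, int, int]]:
    """Level dims, coarsest to finest: ceil-halve until within the leaf cap."""
    levels = [tuple(int(d) for d in dims)]
    while any(d > c for d, c in zip(levels[0], leaf_cap)):
        levels.insert(0, tuple((d + 1) // 2 for d in levels[0]))
    return levels


def _pairwise_mean(a: np.ndarray, axis: int) -> np.ndarray:
    n = a.shape[axis]
    even = (n // 2) * 2
    head = a.take(range(0, even, 2), axis=axis)
    tail = a.take(range(1, even, 2), axis=axis)
    out = 0.5 * (head + tail)
    if n % 2:
        out = np.concatenate([out, a.take([n - 1], axis=axis)], axis=axis)
    return out


def _downsample(arr: np.ndarray, dtype: np.dtype, aggregator: str) -> np.ndarray:
    """Halve each spatial axis: 2x2x2 block mean (round half-up for integer
    dtypes) or block max for sparse signal."""
    if aggregator == "max":
        out = arr.astype(float)
        for axis in range(3):
            n = out.shape[axis]
            even = (n // 2) * 2
            head = out.take(range(0, even, 2), axis=axis)
            tail = out.take(range(1, even, 2), axis=axis)
            red = np.maximum(head, tail)
            if n % 2:
                red = np.concatenate([red, out.take([n - 1], axis=axis)], axis=axis)
            out = red
    else:
        out = arr.astype(float)
        for axis in range(3):
            out = _pairwise_mean(out, axis)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.floor(out + 0.5), info.min, info.max)
    return out.astype(dtype)


def _write_level(arr: np.ndarray, level_dir: Path, tile_size) -> list:
    level_dir.mkdir(parents=True, exist_ok=True)
    tiles = []
    dims = arr.shape[:3]
    for z0 in range(0, dims[2], tile_size[2]):
        for y0 in range(0, dims[1], tile_size[1]):
            for x0 in range(0, dims[0], tile_size[0]):
                x1 = min(x0 + tile_size[0], dims[0])
                y1 = min(y0 + tile_size[1], dims[1])
                z1 = min(z0 + tile_size[2], dims[2])
                tile = arr[x0:x1, y0:y1, z0:z1]
                name = f"t_z{z0}_y{y0}_x{x0}.tif"
                write_volume(Volume(tile.copy()), level_dir / name)
                tiles.append({
                    "offset": [x0, y0, z0],
                    "shape": [x1 - x0, y1 - y0, z1 - z0],
                    "path": f"{level_dir.name}/{name}",
                })
    return tiles


def build_octree(
    src: Volume,
    out,
    leaf_cap=DEFAULT_LEAF_CAP,
    tile_size=DEFAULT_TILE_SIZE,
    aggregator: str = "mean",
) -> OctreeIndex:
    """Build and store the tile pyramid for ``src``; returns its index.

    Level order in the index is coarsest to finest; recursion stops once the
    coarsest dims fit ``leaf_cap`` on every axis.  Output bytes are a pure
    function of the input volume.
    """
    if min(src.dims) < 1:
        raise ValueError("source volume has an empty dimension")
    tile_size = tuple(int(t) for t in tile_size)
    if min(tile_size) < 16:
        raise ValueError("tile_size must be >= 16 per axis")
    leaf_cap = tuple(int(c) for c in leaf_cap)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    pyramids = [src.data]
    while any(d > c for d, c in zip(pyramids[-1].shape[:3], leaf_cap)):
        pyramids.append(_downsample(pyramids[-1], src.data.dtype, aggregator))
    pyramids.reverse()  # coarsest first

    levels = []
    for k, arr in enumerate(pyramids):
        tiles = _write_level(arr, out / f"level_{k}", tile_size)
        levels.append({"dims": list(arr.shape[:3]), "tile_size": list(tile_size),
                       "tiles": tiles})
    index = OctreeIndex(out, levels, src.data.dtype.name, src.n_channels, leaf_cap)
    index.save()
    return index


def resolve_roi(index: OctreeIndex, roi, level: int, target_level: int = None) -> ResolvedRoi:
    """Map an ROI at ``level`` to ``target_level`` (default: finest) and list
    the minimal covering tile set.

    Coordinates scale by ``2**(target - level)`` per axis (floor/ceil so the
    scaled box covers the original footprint).  The tile set is found by
    arithmetic on the tile grid, so the work is a function of the ROI size
    only, not of the total volume size.
    """
    if target_level is None:
        target_level = index.n_levels - 1
    if not 0 <= level < index.n_levels or not 0 <= target_level < index.n_levels:
        raise IndexError(f"level out of range [0, {index.n_levels})")
    if hasattr(roi, "min_corner"):
        lo = np.asarray(roi.min_corner, dtype=int)
        hi = np.asarray(roi.max_corner, dtype=int)
    else:
        lo = np.asarray(roi[0], dtype=int)
        hi = np.asarray(roi[1], dtype=int)
    dims = np.asarray(index.levels[level]["dims"], dtype=int)
    if np.any(lo < 0) or np.any(hi > dims) or np.any(hi <= lo):
        raise IndexError(f"roi {lo}..{hi} out of bounds for level {level} dims {tuple(dims)}")

    shift = target_level - level
    if shift >= 0:
        t_lo = lo * (2**shift)
        t_hi = hi * (2**shift)
    else:
        f = 2 ** (-shift)
        t_lo = lo // f
        t_hi = -(-hi // f)  # ceil division
    t_dims = np.asarray(index.levels[target_level]["dims"], dtype=int)
    t_lo = np.clip(t_lo, 0, t_dims)
    t_hi = np.clip(t_hi, 1, t_dims)

    ts = np.asarray(index.levels[target_level]["tile_size"], dtype=int)
    g_lo = t_lo // ts
    g_hi = -(-t_hi // ts)
    lookup = index.tile_lookup(target_level)
    tiles = []
    examined = 0
    for gx in range(g_lo[0], g_hi[0]):
        for gy in range(g_lo[1], g_hi[1]):
            for gz in range(g_lo[2], g_hi[2]):
                examined += 1
                t = lookup.get((gx * ts[0], gy * ts[1], gz * ts[2]))
                if t is not None:
                    tiles.append(t)
    box = (tuple(int(v) for v in t_lo), tuple(int(v) for v in t_hi))
    return ResolvedRoi(target_level, box, tiles, examined)


def load_block(index: OctreeIndex, resolved: ResolvedRoi) -> Volume:
    """Assemble the resolved tiles into the contiguous requested sub-volume."""
    lo = np.asarray(resolved.box[0], dtype=int)
    hi = np.asarray(resolved.box[1], dtype=int)
    shape = tuple(hi - lo) + (index.channels,)
    out = np.zeros(shape, dtype=np.dtype(index.dtype))
    for t in resolved.tiles:
        path = index.root / t["path"]
        if not path.exists():
            raise IntegrityError(f"missing octree tile {path}")
        tile = read_volume(path)
        off = np.asarray(t["offset"], dtype=int)
        t_hi = off + np.asarray(t["shape"], dtype=int)
        a = np.maximum(lo, off)
        b = np.minimum(hi, t_hi)
        if np.any(b <= a):
            continue
        src = tile.data[a[0]-off[0]:b[0]-off[0], a[1]-off[1]:b[1]-off[1],
                        a[2]-off[2]:b[2]-off[2], :]
        out[a[0]-lo[0]:b[0]-lo[0], a[1]-lo[1]:b[1]-lo[1], a[2]-lo[2]:b[2]-lo[2], :] = src
    return Volume(out)
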