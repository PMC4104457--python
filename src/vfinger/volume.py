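"""3D (multi-channel) image stacks with a fixed coordinate convention.

A :class:`Volume` holds intensities on a voxel grid indexed ``data[x, y, z, c]``.
Coordinates are 0-based and voxel-centered: voxel ``(i, j, k)`` occupies the
half-open cube ``[i-0.5, i+0.5) x [j-0.5, j+0.5) x [k-0.5, k+0.5)``, so
continuous (sub-voxel) coordinates are meaningful everywhere downstream.

On disk, multi-page TIFF is the primary format: pages are Z, page rows are Y,
columns are X, channels are samples-per-pixel.  NRRD and a raw little-endian
array with a JSON sidecar header are also supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["Volume", "IntensityRange", "read_volume", "write_volume", "intensity_range"]


@dataclass
class Volume:
    """A 3D scalar grid with ``C >= 1`` channels, stored as ``(X, Y, Z, C)``."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:
            arr = arr[..., np.newaxis]
        if arr.ndim != 4:
            raise ValueError(f"volume data must be 3D or 4D, got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
            raise ValueError("volume intensities must be finite")
        self.data = arr

    @property
    def dims(self) -> tuple[int, int, int]:
        """Spatial extent (X, Y, Z)."""
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype

    def channel(self, c: int) -> np.ndarray:
        """The (X, Y, Z) array of one channel."""
        if not 0 <= c < self.n_channels:
            raise IndexError(f"channel {c} out of range [0, {self.n_channels})")
        return self.data[..., c]

    def reduced(self) -> np.ndarray:
        """Per-voxel max across channels (what a MIP viewer shows)."""
        if self.n_channels == 1:
            return self.data[..., 0]
        return self.data.max(axis=3)

    def contains(self, p) -> bool:
        """True when continuous point ``p`` lies within the voxel-center bounds."""
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= np.asarray(self.dims) - 1))


@dataclass(frozen=True)
class IntensityRange:
    i_min: float
    i_max: float

    def __post_init__(self) -> None:
        if self.i_min > self.i_max:
            raise ValueError("i_min must be <= i_max")

    @property
    def span(self) -> float:
        return self.i_max - self.i_min


def intensity_range(vol: Volume, channel: int = 0) -> IntensityRange:
    """Exact per-channel intensity (min, max) over all voxels."""
    ch = vol.channel(channel)
    return IntensityRange(float(ch.min()), float(ch.max()))


# ---------------------------------------------------------------------------
# I/O


def _tiff_to_xyzc(arr: np.ndarray, axes: str, path) -> np.ndarray:
    """Normalize a tifffile array+axes string to (X, Y, Z, C)."""
    axes = axes.upper().replace("S", "C")
    # Drop singleton axes we do not model (I = generic sequence is kept as Z).
    axes = axes.replace("I", "Z")
    keep = []
    for i, a in enumerate(axes):
        if a in "XYZC":
            keep.append(a)
        elif arr.shape[i] == 1:
            arr = np.squeeze(arr, axis=len(keep))
        else:
            raise FormatError(f"{path}: ambiguous TIFF axis {a!r} of size {arr.shape[i]}")
    axes = "".join(keep)
    if len(set(axes)) != len(axes):
        raise FormatError(f"{path}: repeated TIFF axes {axes!r}")
    for a in "ZC":
        if a not in axes:
            arr = arr[np.newaxis]
            axes = a + axes
    if sorted(axes) != ["C", "X", "Y", "Z"]:
        raise FormatError(f"{path}: unsupported TIFF axes {axes!r}")
    return np.ascontiguousarray(arr.transpose([axes.index(a) for a in "XYZC"]))


def _read_tiff(path: Path) -> Volume:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
    return Volume(_tiff_to_xyzc(arr, axes, path))


def _write_tiff(vol: Volume, path: Path) -> None:
    import tifffile

    # (X, Y, Z, C) -> pages Z, rows Y, cols X, samples C
    arr = np.ascontiguousarray(vol.data.transpose(2, 1, 0, 3))
    if arr.shape[3] == 1:
        tifffile.imwrite(path, arr[..., 0], metadata={"axes": "ZYX"},
                         photometric="minisblack")
    else:
        tifffile.imwrite(path, arr, metadata={"axes": "ZYXS"}, photometric="minisblack")


def _read_nrrd(path: Path) -> Volume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (Z, Y, X) or (Z, Y, X, C)
    if arr.ndim == 3:
        arr = arr[..., np.newaxis]
    if arr.ndim != 4:
        raise FormatError(f"{path}: unsupported NRRD dimensionality {arr.ndim}")
    spacing = img.GetSpacing()[:3]
    return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0, 3)), voxel_size=tuple(spacing))


def _write_nrrd(vol: Volume, path: Path) -> None:
    import SimpleITK as sitk

    arr = np.ascontiguousarray(vol.data.transpose(2, 1, 0, 3))
    if arr.shape[3] == 1:
        img = sitk.GetImageFromArray(arr[..., 0], isVector=False)
    else:
        img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in vol.voxel_size))
    sitk.WriteImage(img, str(path))


def _read_raw(header_path: Path) -> Volume:
    try:
        header = json.loads(header_path.read_text())
        dims = [int(d) for d in header["dims"]]
        dtype = np.dtype(header["dtype"]).newbyteorder("<")
        channels = int(header.get("channels", 1))
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{header_path}: bad raw header ({exc})") from exc
    raw_path = header_path.parent / header.get("raw", header_path.stem + ".raw")
    if not raw_path.exists():
        raise FormatError(f"{header_path}: raw file {raw_path} not found")
    flat = np.fromfile(raw_path, dtype=dtype)
    expect = dims[0] * dims[1] * dims[2] * channels
    if flat.size != expect:
        raise FormatError(
            f"{raw_path}: expected {expect} scalars for dims {dims} x {channels} "
            f"channels, found {flat.size}"
        )
    arr = flat.reshape(dims[2], dims[1], dims[0], channels)  # Z, Y, X, C on disk
    return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0, 3)))


def _write_raw(vol: Volume, header_path: Path) -> None:
    raw_path = header_path.with_suffix(".raw")
    header = {
        "dims": list(vol.dims),
        "dtype": vol.data.dtype.name,
        "channels": vol.n_channels,
        "raw": raw_path.name,
    }
    header_path.write_text(json.dumps(header, indent=1))
    np.ascontiguousarray(vol.data.transpose(2, 1, 0, 3)).astype(
        vol.data.dtype.newbyteorder("<")
    ).tofile(raw_path)


_READERS = {
    ".tif": _read_tiff,
    ".tiff": _read_tiff,
    ".nrrd": _read_nrrd,
    ".nhdr": _read_nrrd,
    ".json": _read_raw,
}
_WRITERS = {
    ".tif": _write_tiff,
    ".tiff": _write_tiff,
    ".nrrd": _write_nrrd,
    ".json": _write_raw,
}


def read_volume(path) -> Volume:
    """Read a multi-page TIFF, NRRD, or raw+JSON volume, normalized to (X, Y, Z, C).

    Raises :class:`FormatError` naming the file when the format cannot be
    identified or its axis metadata is ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise FormatError(f"{path}: unsupported volume format {path.suffix!r}")
    try:
        return reader(path)
    except FormatError:
        raise
    except Exception as exc:  # truncated / corrupt files surface here
        raise FormatError(f"{path}: unreadable volume ({exc})") from exc


def write_volume(vol: Volume, path) -> None:
    """Write ``vol`` so that :func:`read_volume` roundtrips it bit-exactly."""
    path = Path(path)
    writer = _WRITERS.get(path.suffix.lower())
    if writer is None:
        raise FormatError(f"{path}: unsupported volume format {path.suffix!r}")
    writer(vol, path)
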