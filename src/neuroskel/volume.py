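"""Dense image volume container and TIFF input/output.

A :class:`DenseVolume` is the dense working set of the pipeline: a 3D
intensity grid in (z, y, x) axis order together with its physical voxel
size in micrometres.  All stages that touch every voxel (destriping,
debleaching, deconvolution, thresholding) operate on this container;
downstream stages work on sparse views of it.

Axis convention: arrays are indexed ``[z, y, x]``; ``voxel_size`` is the
matching ``(z, y, x)`` triple in um/voxel.  Physical coordinates use the
voxel-centre convention, ``position_um = index * voxel_size``.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["DenseVolume", "read_tiff", "write_tiff", "read_series", "write_series"]


@dataclass
class DenseVolume:
    """A 3D non-negative intensity grid with anisotropic physical voxel size.

    Parameters
    ----------
    data:
        3D array in (z, y, x) order.  8/16-bit integer or floating point;
        intensities must be non-negative.
    voxel_size:
        (z, y, x) voxel extent in micrometres; all components positive.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype_bits(self):
        """8, 16 or the string 'float' describing the stored sample format."""
        dt = self.data.dtype
        if np.issubdtype(dt, np.floating):
            return "float"
        return dt.itemsize * 8

    def astype_float(self) -> "DenseVolume":
        """Return a float32 view-copy of the volume (integer inputs promoted)."""
        if self.data.dtype == np.float32:
            return self
        return DenseVolume(self.data.astype(np.float32), self.voxel_size)

    def like(self, data: np.ndarray) -> "DenseVolume":
        """A new volume with the same voxel size, clamped back to this dtype.

        Float data written back into an integer container is clamped to the
        dtype range and rounded; float containers pass through with a >= 0
        clamp only.
        """
        if np.issubdtype(self.data.dtype, np.integer):
            info = np.iinfo(self.data.dtype)
            out = np.clip(np.rint(data), info.min if info.min > 0 else 0, info.max)
            return DenseVolume(out.astype(self.data.dtype), self.voxel_size)
        return DenseVolume(np.maximum(data, 0).astype(self.data.dtype, copy=False), self.voxel_size)


def read_tiff(path: str | os.PathLike, voxel_size=(1.0, 1.0, 1.0)) -> DenseVolume:
    """Read a 3D TIFF stack (or a single slice, promoted to 1 x Y x X)."""
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    return DenseVolume(arr, voxel_size)


def write_tiff(volume: DenseVolume, path: str | os.PathLike) -> None:
    tifffile.imwrite(os.fspath(path), volume.data)


_SLICE_RE = re.compile(r"(\d+)\.tiff?$", re.IGNORECASE)


def read_series(directory: str | os.PathLike, voxel_size=(1.0, 1.0, 1.0)) -> DenseVolume:
    """Read a per-slice TIFF series, filename-sorted by zero-padded slice index."""
    directory = os.fspath(directory)
    names = [n for n in sorted(os.listdir(directory)) if _SLICE_RE.search(n)]
    if not names:
        raise FileNotFoundError(f"no numbered .tif slices in {directory}")
    slices = [tifffile.imread(os.path.join(directory, n)) for n in names]
    return DenseVolume(np.stack(slices, axis=0), voxel_size)


def write_series(volume: DenseVolume, directory: str | os.PathLike, prefix: str = "z") -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    width = max(4, len(str(volume.shape[0] - 1)))
    for i in range(volume.shape[0]):
        tifffile.imwrite(os.path.join(directory, f"{prefix}{i:0{width}d}.tif"), volume.data[i])
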