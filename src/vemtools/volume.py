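"""Raster primitives shared by the whole toolkit.

A :class:`Volume` is an anisotropic 3D grid — grayscale, binary or
integer-labeled — with a physical voxel pitch in nanometres and an integer
offset placing it in a global voxel frame.  Conventions used everywhere:

* axis order is ``(x, y, z)``; ``data[i, j, k]`` is the voxel at index
  ``(i, j, k)``,
* indices are 0-based and extents half-open,
* the physical position of a voxel centre is ``(offset + index) * voxel_size``
  (nm),
* label 0 is reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "connectivity_struct",
    "connected_components",
    "erode_ball",
    "ball_struct",
    "downsample_area",
    "read_volume",
    "write_volume",
]

_ALLOWED_3D = (6, 18, 26)
_ALLOWED_2D = (4, 8)


@dataclass
class Volume:
    """A 3D raster with physical voxel size (nm) and global-frame offset."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (14.0, 14.0, 25.0)
    offset: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs
        self.offset = tuple(int(o) for o in self.offset)
        if np.issubdtype(self.data.dtype, np.signedinteger) and self.data.size:
            if self.data.min() < 0:
                raise ValueError("label volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_binary(self) -> bool:
        if self.data.dtype == bool:
            return True
        return bool(np.isin(self.data, (0, 1)).all())

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid (voxel size and offset) as this one."""
        return Volume(data, self.voxel_size, self.offset)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and self.voxel_size == other.voxel_size
            and self.offset == other.offset
        )

    def world_to_index(self, points_nm: np.ndarray) -> np.ndarray:
        """Map physical nm positions to voxel indices (floor to voxel)."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        idx = np.floor(pts / np.asarray(self.voxel_size) + 0.5).astype(int)
        return idx - np.asarray(self.offset)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + np.asarray(self.offset)) * np.asarray(self.voxel_size)


def connectivity_struct(kind: int, ndim: int = 3) -> np.ndarray:
    """Binary structuring element for a named voxel neighbourhood.

    ``kind`` is 6/18/26 for 3D, 4/8 for 2D — the standard digital-topology
    neighbourhoods (face / face+edge / face+edge+corner adjacency).
    """
    if ndim == 3:
        if kind not in _ALLOWED_3D:
            raise ValueError(f"3D connectivity must be one of {_ALLOWED_3D}, got {kind}")
        rank = {6: 1, 18: 2, 26: 3}[kind]
    elif ndim == 2:
        if kind not in _ALLOWED_2D:
            raise ValueError(f"2D connectivity must be one of {_ALLOWED_2D}, got {kind}")
        rank = {4: 1, 8: 2}[kind]
    else:
        raise ValueError("only 2D and 3D connectivities are defined")
    return ndimage.generate_binary_structure(ndim, rank)


def _relabel_first_encounter(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..K in raster-scan order of each component's first voxel."""
    flat = labels.ravel()
    nz = flat != 0
    if not nz.any():
        return labels
    seen, first_idx = np.unique(flat[nz], return_index=True)
    order = np.argsort(first_idx, kind="stable")
    mapping = np.zeros(int(seen.max()) + 1, dtype=labels.dtype)
    mapping[seen[order]] = np.arange(1, len(seen) + 1, dtype=labels.dtype)
    return mapping[labels]


def connected_components(mask: Volume, conn: int = 26) -> Volume:
    """Label connected components of a binary volume.

    Background stays 0; components are numbered 1..K in deterministic
    raster-scan order of their first voxel.
    """
    if not mask.is_binary():
        raise ValueError("connected_components requires a binary volume")
    struct = connectivity_struct(conn, ndim=3)
    labels, _ = ndimage.label(np.asarray(mask.data, dtype=bool), structure=struct)
    labels = _relabel_first_encounter(labels.astype(np.int32))
    return mask.like(labels)


def ball_struct(radius: int, voxel_size: tuple[float, float, float] | None = None) -> np.ndarray:
    """Digitized ball structuring element.

    By default the ball is Euclidean in voxel index space (radius in voxels,
    anisotropy ignored).  If ``voxel_size`` is given the ball is metric: the
    radius is in nm and each axis is scaled by its voxel pitch.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if voxel_size is None:
        r = int(radius)
        grids = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        return (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= r * r
    extents = [max(int(np.floor(radius / s)), 0) for s in voxel_size]
    axes = [np.arange(-e, e + 1) * s for e, s in zip(extents, voxel_size)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return (gx**2 + gy**2 + gz**2) <= radius * radius


def erode_ball(mask: Volume, radius: int, metric_nm: bool = False) -> Volume:
    """Morphological erosion with a digitized ball.

    ``radius`` is in voxels (isotropic in index space) unless ``metric_nm``
    is set, in which case it is in nm and the ball respects the voxel pitch.
    Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if not mask.is_binary():
        raise ValueError("erode_ball requires a binary volume")
    data = np.asarray(mask.data, dtype=bool)
    if radius == 0:
        return mask.like(data.copy())
    struct = ball_struct(radius, mask.voxel_size if metric_nm else None)
    return mask.like(ndimage.binary_erosion(data, structure=struct))


def downsample_area(img: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downsampling of a 2D plane by an integer factor.

    Each output pixel is the arithmetic mean of its ``factor x factor``
    block; edge blocks are averaged over the pixels actually present, so the
    global mean is preserved exactly when ``factor`` divides both dimensions.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("downsample_area expects a 2D plane")
    if factor == 1:
        return img.copy()
    h, w = img.shape
    ih = np.arange(0, h, factor)
    iw = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(img, ih, axis=0), iw, axis=1)
    ch = np.minimum(ih + factor, h) - ih
    cw = np.minimum(iw + factor, w) - iw
    return sums / np.outer(ch, cw)


def write_volume(vol: Volume, path: str | Path, dataset: str = "volume") -> Path:
    """Write a volume to an HDF5 container; voxel_size/offset go to attrs."""
    import h5py

    path = Path(path)
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        ds = f.create_dataset(dataset, data=vol.data, compression="gzip")
        ds.attrs["voxel_size"] = np.asarray(vol.voxel_size, dtype=float)
        ds.attrs["offset"] = np.asarray(vol.offset, dtype=np.int64)
    return path


def read_volume(path: str | Path, dataset: str = "volume") -> Volume:
    """Read a volume written by :func:`write_volume` (bit-exact round trip)."""
    import h5py

    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not found in {path}")
        ds = f[dataset]
        data = ds[()]
        voxel_size = tuple(float(v) for v in ds.attrs.get("voxel_size", (1.0, 1.0, 1.0)))
        offset = tuple(int(o) for o in ds.attrs.get("offset", (0, 0, 0)))
    return Volume(data, voxel_size, offset)
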