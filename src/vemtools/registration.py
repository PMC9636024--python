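"""Block-wise affine registration from landmark correspondences.

Corresponding points clicked in two image stacks (e.g. somata and vessel
branch points visible in both a functional light-microscopy stack and the
EM volume) drive a piecewise-affine mapping: the source domain is divided
into a regular grid of blocks and each block receives its own
least-squares affine, fitted to all landmark pairs whose source point lies
within the block's surround.  Blocks without enough well-conditioned
points fall back to the global affine and are flagged.  Transforms are
piecewise-constant across blocks (no blending), mirroring per-block
application in the original workflow; optional trilinear blending of
block corners is available behind a flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tiling import StageTransform, fit_stage_transform

__all__ = ["LandmarkSet", "BlockGrid", "fit_blockwise_affine", "apply_blockwise", "loo_block_errors"]


@dataclass
class LandmarkSet:
    """Paired source/target points in physical units, with optional tags."""

    src: np.ndarray  # (n, 3)
    dst: np.ndarray  # (n, 3)
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 3:
            raise ValueError("src and dst must be matching (n, 3) arrays")
        if len(self.src) < 1:
            raise ValueError("need at least one landmark pair")
        if not (np.isfinite(self.src).all() and np.isfinite(self.dst).all()):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.src)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        src, dst, tags = [], [], []
        with open(path) as f:
            for row in csv.DictReader(f):
                src.append([float(row["sx"]), float(row["sy"]), float(row["sz"])])
                dst.append([float(row["tx"]), float(row["ty"]), float(row["tz"])])
                tags.append(row.get("tag", ""))
        return cls(np.array(src), np.array(dst), tags)

    def to_csv(self, path: str | Path) -> Path:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["sx", "sy", "sz", "tx", "ty", "tz", "tag"])
            for i in range(len(self)):
                tag = self.tags[i] if self.tags else ""
                w.writerow([*self.src[i], *self.dst[i], tag])
        return Path(path)


@dataclass
class BlockGrid:
    """Regular block partition of the source domain with per-block affines."""

    origin: np.ndarray
    block_size: np.ndarray  # physical units per block, default (42, 28, 2)
    grid_shape: tuple[int, int, int]
    surround: np.ndarray  # surround radius per axis
    transforms: np.ndarray | None = None  # (nx, ny, nz, 3, 4)
    fallback: np.ndarray | None = None  # bool per block: used global affine
    global_transform: StageTransform | None = None
    n_points: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.transforms is not None

    def block_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Block index of each point; second output marks points outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.block_size).astype(int)
        shape = np.asarray(self.grid_shape)
        outside = np.any((idx < 0) | (idx >= shape), axis=1)
        return np.clip(idx, 0, shape - 1), outside


def _degenerate(src: np.ndarray) -> bool:
    centered = src - src.mean(axis=0)
    scale = max(1.0, float(np.abs(src).max()))
    return np.linalg.matrix_rank(centered, tol=1e-9 * scale) < 3


def fit_blockwise_affine(
    landmarks: LandmarkSet,
    block_size=(42.0, 28.0, 2.0),
    surround=None,
    min_points: int = 4,
) -> BlockGrid:
    """Fit one least-squares affine per block of the source domain.

    Each block's affine uses every landmark whose source point lies within
    the block dilated by ``surround`` (default: one block size per axis).
    Blocks with fewer than ``min_points`` usable points, or a degenerate
    configuration, fall back to the global affine and are flagged.
    """
    if len(landmarks) < 4:
        raise ValueError("need at least 4 landmarks for any affine")
    block_size = np.asarray(block_size, dtype=float)
    if np.any(block_size <= 0):
        raise ValueError("block_size must be positive")
    surround = block_size.copy() if surround is None else np.asarray(surround, dtype=float)

    src, dst = landmarks.src, landmarks.dst
    origin = src.min(axis=0)
    extent = src.max(axis=0) - origin
    grid_shape = tuple(int(max(1, np.ceil(e / b))) for e, b in zip(extent, block_size))
    glob = fit_stage_transform(src, dst)

    nx, ny, nz = grid_shape
    transforms = np.empty((nx, ny, nz, 3, 4))
    fallback = np.zeros((nx, ny, nz), dtype=bool)
    n_points = np.zeros((nx, ny, nz), dtype=int)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                lo = origin + np.array([ix, iy, iz]) * block_size - surround
                hi = origin + (np.array([ix, iy, iz]) + 1) * block_size + surround
                sel = np.all((src >= lo) & (src <= hi), axis=1)
                n_points[ix, iy, iz] = int(sel.sum())
                if sel.sum() >= min_points and not _degenerate(src[sel]):
                    transforms[ix, iy, iz] = fit_stage_transform(src[sel], dst[sel]).matrix
                else:
                    transforms[ix, iy, iz] = glob.matrix
                    fallback[ix, iy, iz] = True
    return BlockGrid(
        origin=origin,
        block_size=block_size,
        grid_shape=grid_shape,
        surround=surround,
        transforms=transforms,
        fallback=fallback,
        global_transform=glob,
        n_points=n_points,
    )


def apply_blockwise(grid: BlockGrid, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map points through their containing block's affine.

    Points outside the grid use the nearest block and are flagged in the
    second output.
    """
    if not grid.fitted:
        raise ValueError("grid has no fitted transforms")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx, outside = grid.block_index(pts)
    out = np.empty_like(pts)
    for i, (p, bi) in enumerate(zip(pts, idx)):
        m = grid.transforms[tuple(bi)]
        out[i] = m[:, :3] @ p + m[:, 3]
    return out, outside


def loo_block_errors(
    landmarks: LandmarkSet,
    block_size=(42.0, 28.0, 2.0),
    surround=None,
    min_points: int = 4,
) -> dict[tuple[int, int, int], float]:
    """Leave-one-out mapping error per block (mean over its landmarks).

    For each landmark inside a block's surround, the block affine is refit
    without it and the residual at the held-out landmark recorded.  Blocks
    keep a finite error; removing a landmark never affects blocks whose
    surround excludes it.
    """
    grid = fit_blockwise_affine(landmarks, block_size, surround, min_points)
    src, dst = landmarks.src, landmarks.dst
    errors: dict[tuple[int, int, int], float] = {}
    nx, ny, nz = grid.grid_shape
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                lo = grid.origin + np.array([ix, iy, iz]) * grid.block_size - grid.surround
                hi = grid.origin + (np.array([ix, iy, iz]) + 1) * grid.block_size + grid.surround
                sel = np.flatnonzero(np.all((src >= lo) & (src <= hi), axis=1))
                res = []
                for li in sel:
                    rest = np.setdiff1d(sel, [li])
                    if len(rest) >= min_points and not _degenerate(src[rest]):
                        t = fit_stage_transform(src[rest], dst[rest])
                        res.append(float(np.linalg.norm(t.apply(src[li])[0] - dst[li])))
                if res:
                    errors[(ix, iy, iz)] = float(np.mean(res))
    return errors
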