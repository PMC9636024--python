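"""X-ray-targeted adaptive tile planning for block-face EM acquisition.

A low-resolution anatomy mask (from micro-CT, registered to the stage by a
least-squares affine) restricts imaging to the tissue: per section,
columns of fixed scan width step across the mask and each column's
occupied y-intervals are covered by elongated tiles of bounded length,
consecutive tiles overlapping by a fixed margin.  Positioning moves are
counted one per tile, and the coverage fraction — scanned voxels over the
mask's cuboid bounding box — quantifies the saving over naive rectangular
mosaics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import Volume

__all__ = ["StageTransform", "TilePlan", "fit_stage_transform", "plan_tiles", "plan_summary"]


@dataclass
class StageTransform:
    """Affine map (3x4 matrix) from mask-grid to stage coordinates."""

    matrix: np.ndarray  # (3, 4)
    residuals: np.ndarray  # per-point Euclidean residuals

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :3].T + self.matrix[:, 3]


@dataclass
class TilePlan:
    tiles: pd.DataFrame  # section, x_start, x_width, y_start, y_length
    n_tiles: int
    n_moves: int
    scanned_voxels: int
    bbox_voxels: int
    bbox_voxels_sectionwise: int
    coverage_fraction: float
    coverage_fraction_sectionwise: float
    tile_width: int
    params: dict = field(default_factory=dict)


def fit_stage_transform(src: np.ndarray, dst: np.ndarray) -> StageTransform:
    """Least-squares affine from >=4 non-coplanar point correspondences."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if len(src) < 4:
        raise ValueError("need at least 4 correspondences for a 3D affine")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("degenerate (coplanar/collinear) correspondence configuration")
    A = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    matrix = coef.T  # (3, 4)
    resid = np.linalg.norm(A @ coef - dst, axis=1)
    return StageTransform(matrix, resid)


def _cover_interval(lo: int, hi: int, y_min: int, y_max: int, overlap: int,
                    bound: int) -> list[tuple[int, int]]:
    """Tiles (start, length) covering [lo, hi) with lengths in [y_min, y_max]."""
    L = hi - lo
    step = y_max - overlap
    k = max(1, int(np.ceil((L - overlap) / step))) if L > y_max else 1
    tiles = []
    for i in range(k):
        start = lo + i * step
        if i == k - 1:
            end = hi
            length = end - start
            if length < y_min:
                start = max(0, min(end - y_min, lo))
                length = min(max(y_min, end - start), y_max)
        else:
            length = y_max
        start = max(0, min(start, bound - length))
        tiles.append((start, length))
    return tiles


def plan_tiles(
    mask: Volume,
    tile_width: int,
    y_min: int = 1,
    y_max: int = 25000,
    overlap: int = 0,
) -> TilePlan:
    """Plan elongated tiles covering the mask of every section.

    Sections are the z-slices of the mask volume.  Columns of width
    ``tile_width`` step across each section's mask x-extent; within a
    column every maximal occupied y-interval is covered by tiles of length
    in [y_min, y_max], consecutive tiles overlapping by ``overlap``.  One
    positioning move is counted per tile.
    """
    if not (tile_width > overlap >= 0):
        raise ValueError("require tile_width > overlap >= 0")
    if y_min > y_max or y_min < 1:
        raise ValueError("require 1 <= y_min <= y_max")
    if y_max <= overlap:
        raise ValueError("require y_max > overlap")
    data = np.asarray(mask.data, dtype=bool)
    X, Y, Z = data.shape
    rows = []
    scanned = 0
    bbox_sec = 0
    for z in range(Z):
        sec = data[:, :, z]
        if not sec.any():
            continue
        xs = np.flatnonzero(sec.any(axis=1))
        ys = np.flatnonzero(sec.any(axis=0))
        bbox_sec += (xs[-1] - xs[0] + 1) * (ys[-1] - ys[0] + 1)
        covered = np.zeros_like(sec)
        x0 = xs[0]
        col_starts = list(range(x0, xs[-1] + 1, tile_width))
        # keep the last column flush with the mask bounding box (overlapping
        # its neighbour) so the scanned area stays inside the bounding box
        if col_starts and col_starts[-1] + tile_width > xs[-1] + 1:
            col_starts[-1] = max(x0, xs[-1] + 1 - tile_width)
        for cx in dict.fromkeys(col_starts):
            col = sec[cx : cx + tile_width, :]
            occ = np.flatnonzero(col.any(axis=0))
            if len(occ) == 0:
                continue
            # maximal runs of consecutive occupied y
            breaks = np.flatnonzero(np.diff(occ) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(occ) - 1]])
            for s, e in zip(starts, ends):
                lo, hi = int(occ[s]), int(occ[e]) + 1
                for ty, tl in _cover_interval(lo, hi, y_min, y_max, overlap, Y):
                    rows.append(
                        {
                            "section": z,
                            "x_start": int(cx),
                            "x_width": int(min(tile_width, X - cx)),
                            "y_start": int(ty),
                            "y_length": int(tl),
                        }
                    )
                    covered[cx : cx + tile_width, ty : ty + tl] = True
        scanned += int(covered.sum())
    tiles = pd.DataFrame(
        rows, columns=["section", "x_start", "x_width", "y_start", "y_length"]
    )
    if data.any():
        occ = np.argwhere(data)
        ext = occ.max(axis=0) - occ.min(axis=0) + 1
        bbox = int(ext[0] * ext[1] * ext[2])
    else:
        bbox = 0
    n_tiles = len(tiles)
    return TilePlan(
        tiles=tiles,
        n_tiles=n_tiles,
        n_moves=n_tiles,
        scanned_voxels=scanned,
        bbox_voxels=bbox,
        bbox_voxels_sectionwise=bbox_sec,
        coverage_fraction=scanned / bbox if bbox else 0.0,
        coverage_fraction_sectionwise=scanned / bbox_sec if bbox_sec else 0.0,
        tile_width=tile_width,
        params={"y_min": y_min, "y_max": y_max, "overlap": overlap},
    )


def plan_summary(plan: TilePlan, n_length_bins: int = 10) -> dict:
    """Totals and a tile-length histogram consistent with the tile table."""
    lengths = plan.tiles["y_length"].to_numpy()
    if len(lengths):
        hist, edges = np.histogram(lengths, bins=n_length_bins)
    else:
        hist, edges = np.array([], dtype=int), np.array([])
    return {
        "n_tiles": int(plan.n_tiles),
        "n_moves": int(plan.n_moves),
        "n_sections": int(plan.tiles["section"].nunique()) if len(lengths) else 0,
        "scanned_voxels": int(plan.scanned_voxels),
        "bbox_voxels": int(plan.bbox_voxels),
        "coverage_fraction": float(plan.coverage_fraction),
        "coverage_fraction_sectionwise": float(plan.coverage_fraction_sectionwise),
        "tile_length_histogram": {
            "counts": hist.tolist(),
            "bin_edges": edges.tolist(),
        },
    }
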