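"""Post-processing of tissue-classifier outputs.

Two stages that turn voxel-wise CNN predictions into usable masks and
objects: a defocus detector operating on contrast-normalized 8-bit planes
(Gaussian smoothing, discrete Laplacian, windowed standard deviation,
128x in-plane area-average downsampling, fixed threshold), and a soma
candidate extractor that zeroes excluded classes, erodes to break false
mergers and keeps nucleus components above a volume threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, connected_components, downsample_area, erode_ball

__all__ = ["DefocusParams", "SomaParams", "defocus_mask", "soma_candidates", "clahe_planes"]

# 5-point discrete Laplacian stencil
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class DefocusParams:
    """Defocus filter-chain parameters (threshold on the 8-bit scale)."""

    gaussian_sigma: float = 1.0
    std_window: int = 21
    downsample_factor: int = 128
    threshold: float = 57.0  # strict less-than marks a site defocused

    def __post_init__(self) -> None:
        if min(self.gaussian_sigma, self.std_window, self.downsample_factor) <= 0:
            raise ValueError("all defocus parameters must be positive")


@dataclass
class SomaParams:
    exclusion_classes: set[str] = field(default_factory=lambda: {"nonneuropil", "soma"})
    erosion_radius: int = 5
    min_volume: int = 1000  # strict greater-than, in voxels of the input grid

    def __post_init__(self) -> None:
        if self.erosion_radius < 0 or self.min_volume < 0:
            raise ValueError("erosion_radius and min_volume must be non-negative")


def clahe_planes(stack: Volume, kernel_size: int = 64, clip_limit: float = 2.0) -> Volume:
    """Optional CLAHE normalization of each plane to 8-bit.

    Tile size and clip limit are recorded here as the package's fixed
    defaults so runs are reproducible; pre-normalized input can be passed
    to :func:`defocus_mask` directly.
    """
    from skimage import exposure

    data = np.asarray(stack.data)
    out = np.empty_like(data, dtype=np.uint8)
    for k in range(data.shape[2]):
        eq = exposure.equalize_adapthist(
            data[:, :, k], kernel_size=kernel_size, clip_limit=clip_limit / 100.0
        )
        out[:, :, k] = np.round(eq * 255).astype(np.uint8)
    return stack.like(out)


def _windowed_std(plane: np.ndarray, window: int) -> np.ndarray:
    """Population std over a centered window, truncated at plane edges."""
    ones = np.ones_like(plane)
    # constant-mode box sums divided by the true (edge-truncated) counts
    counts = ndimage.uniform_filter(ones, size=window, mode="constant") * window**2
    s1 = ndimage.uniform_filter(plane, size=window, mode="constant") * window**2
    s2 = ndimage.uniform_filter(plane**2, size=window, mode="constant") * window**2
    mean = s1 / counts
    var = np.maximum(s2 / counts - mean**2, 0.0)
    return np.sqrt(var)


def defocus_mask(stack: Volume, params: DefocusParams | None = None) -> Volume:
    """Detect defocused regions of an 8-bit contrast-normalized stack.

    Per plane: Gaussian smoothing, discrete 5-point Laplacian, standard
    deviation over a centered (edge-truncated) window, area-average
    downsampling in-plane, then sites with value below the threshold are
    marked defocused (True).  Output is a binary volume at the downsampled
    in-plane resolution with the voxel size scaled accordingly.
    """
    params = params or DefocusParams()
    data = np.asarray(stack.data)
    if data.ndim != 3:
        raise ValueError("defocus_mask expects a 3D stack of planes")
    f = params.downsample_factor
    out_planes = []
    for k in range(data.shape[2]):
        plane = data[:, :, k].astype(float)
        g = ndimage.gaussian_filter(plane, params.gaussian_sigma)
        lap = ndimage.convolve(g, _LAPLACIAN, mode="nearest")
        std = _windowed_std(lap, params.std_window)
        ds = downsample_area(std, f)
        out_planes.append(ds < params.threshold)
    mask = np.stack(out_planes, axis=2)
    sx, sy, sz = stack.voxel_size
    return Volume(mask, (sx * f, sy * f, sz), stack.offset)


def soma_candidates(
    nucleus_pred: Volume,
    class_maps: dict[str, Volume] | None = None,
    params: SomaParams | None = None,
    conn: int = 26,
) -> tuple[Volume, pd.DataFrame]:
    """Extract soma/nucleus candidate objects from binarized predictions.

    Voxels belonging to any excluded class are zeroed, connected components
    are computed, the mask is eroded with a digitized ball to break false
    mergers, components are recomputed, and only objects strictly larger
    than ``min_volume`` voxels are retained.  Returns the label volume and
    a table (id, volume_voxels, centroid nm) sorted by id.
    """
    params = params or SomaParams()
    class_maps = class_maps or {}
    if not nucleus_pred.is_binary():
        raise ValueError("nucleus_pred must be binary (binarize the prediction first)")
    mask = np.asarray(nucleus_pred.data, dtype=bool).copy()
    for name, vol in class_maps.items():
        if name not in params.exclusion_classes:
            continue
        if not nucleus_pred.same_grid(vol):
            raise ValueError(f"class map {name!r} is not on the nucleus grid")
        mask &= ~np.asarray(vol.data, dtype=bool)

    vol0 = nucleus_pred.like(mask)
    _ = connected_components(vol0, conn)  # initial segmentation (per protocol)
    eroded = erode_ball(vol0, params.erosion_radius)
    labels = connected_components(eroded, conn)

    ids, volumes, centroids = [], [], []
    vs = np.asarray(nucleus_pred.voxel_size)
    off = np.asarray(nucleus_pred.offset)
    lab_data = labels.data
    for lab in range(1, int(lab_data.max()) + 1 if lab_data.size else 1):
        vox = np.argwhere(lab_data == lab)
        if len(vox) > params.min_volume:
            ids.append(lab)
            volumes.append(len(vox))
            centroids.append((vox.mean(axis=0) + off) * vs)
    keep = np.zeros(int(lab_data.max()) + 1 if lab_data.size else 1, dtype=lab_data.dtype)
    for new, old in enumerate(ids, start=1):
        keep[old] = new
    out = keep[lab_data]
    table = pd.DataFrame(
        {
            "id": np.arange(1, len(ids) + 1),
            "volume_voxels": volumes,
            "cx_nm": [c[0] for c in centroids],
            "cy_nm": [c[1] for c in centroids],
            "cz_nm": [c[2] for c in centroids],
        }
    )
    return nucleus_pred.like(out), table
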