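"""3D morphology of segmented uptake regions.

Volume (voxel counting), surface area (marching-cubes isosurface mesh, which
avoids the systematic ~1.5x overestimate of voxel-face counting on curved
objects), sphericity psi = pi^(1/3) (6V)^(2/3) / A (1 for a perfect sphere),
and the box-counting fractal dimension of the binary mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure


@dataclass
class ShapeMetrics:
    volume_mm3: float
    surface_area_mm2: float
    sphericity: float
    fractal_dimension: float


def mask_volume(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Volume in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * float(np.prod(spacing))


def mask_surface_area(mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                      smoothing: float = 0.5) -> float:
    """Surface area in mm^2 of the 0.5-level isosurface of the binary mask.

    The indicator is lightly Gaussian-smoothed (``smoothing`` voxels)
    before meshing: raw marching cubes on a binary field overestimates
    curved surfaces by ~8 % (staircase bevels) while oversmoothing rounds
    away edges of polyhedral shapes; 0.5 voxels balances the two.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask.astype(float), 4)  # close the surface at the borders
    if smoothing > 0:
        from scipy import ndimage

        smoothed = ndimage.gaussian_filter(padded, smoothing)
        # tiny masks can be smoothed entirely below the isosurface level;
        # mesh the raw indicator then
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5,
                                              spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def sphericity(volume_mm3: float, surface_area_mm2: float) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A; dimensionless, 1 for a sphere."""
    if volume_mm3 <= 0 or surface_area_mm2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / surface_area_mm2


def fractal_dimension(mask: np.ndarray, drop_coarsest: int = 2) -> float:
    """Box-counting fractal dimension of a binary mask.

    Counts occupied s^3 boxes for s = 1, 2, 4, ... up to half the smallest
    mask extent and fits log N(s) against log(1/s) by least squares. When
    five or more scales are available the two coarsest are excluded from
    the fit (they carry the largest finite-size bias).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must occupy at least 2 voxels")
    idx = np.nonzero(mask)
    lo = [a.min() for a in idx]
    hi = [a.max() + 1 for a in idx]
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    min_extent = min(sub.shape)
    k = max(int(math.floor(math.log2(max(min_extent, 2)))) - 1, 1)
    sizes = [2 ** p for p in range(k + 1)]

    counts = []
    for s in sizes:
        shape = [int(np.ceil(d / s)) for d in sub.shape]
        pad = [(0, sh * s - d) for sh, d in zip(shape, sub.shape)]
        blocks = np.pad(sub, pad).reshape(shape[0], s, shape[1], s, shape[2], s)
        counts.append(int(blocks.any(axis=(1, 3, 5)).sum()))
    if len(sizes) < 2:
        raise ValueError("degenerate box-count fit: a single scale only")
    if len(sizes) >= 5 and drop_coarsest:
        sizes = sizes[:-drop_coarsest]
        counts = counts[:-drop_coarsest]
    slope, _ = np.polyfit(np.log([1.0 / s for s in sizes]), np.log(counts), 1)
    return float(slope)


def shape_metrics(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ShapeMetrics:
    """All shape descriptors of one segmented lesion."""
    v = mask_volume(mask, spacing)
    a = mask_surface_area(mask, spacing)
    return ShapeMetrics(
        volume_mm3=v,
        surface_area_mm2=a,
        sphericity=sphericity(v, a),
        fractal_dimension=fractal_dimension(mask),
    )
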