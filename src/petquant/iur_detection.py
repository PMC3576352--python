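"""Automatic detection of interesting uptake regions (IURs) and seed placement.

Detection is a threshold-interval encoder over the SUV volume followed by
connected-component labeling: voxels whose SUV lies in [lower, upper] form
candidate regions; each surviving component is an IUR. The default lower
threshold is 40 % of the global SUV_max — the conventional clinical uptake
threshold — with an absolute-SUV mode available.

Seeding turns each IUR into random-walker input: voxels at the region's
SUV_max become foreground seeds, and a breadth-first expansion outward from
the region marks the nearest voxels with SUV <= SUV_max / N as background
seeds (N = 2.5 by default, i.e. the same 40 % convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import PetVolume

log = logging.getLogger(__name__)


class SeedingError(RuntimeError):
    """No valid background seed could be found for a region."""


def connectivity_structure(mode: str = "inplane8") -> np.ndarray:
    """3x3x3 adjacency structuring element.

    ``inplane8``: 8-connectivity within a slice plus face adjacency across
    slices (the 2D labeling convention lifted to 3D); ``full26`` and ``face6``
    are the standard 3D alternatives. Slices are the (x, y) planes, stacked
    along the third axis.
    """
    if mode == "inplane8":
        s = np.zeros((3, 3, 3), dtype=bool)
        s[:, :, 1] = True
        s[1, 1, 0] = s[1, 1, 2] = True
        return s
    if mode == "full26":
        return np.ones((3, 3, 3), dtype=bool)
    if mode == "face6":
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unknown connectivity mode {mode!r}")


@dataclass
class EncoderConfig:
    """Threshold-interval encoder configuration.

    ``lower`` is interpreted per ``mode``: a fraction of the global SUV_max
    (``mode='fraction'``, default 0.4) or an absolute SUV. ``upper`` is always
    absolute (default +inf). Components smaller than ``min_region_voxels``
    are discarded as noise.
    """

    lower: float = 0.4
    upper: float = np.inf
    mode: str = "fraction"  # 'fraction' | 'absolute'
    min_region_voxels: int = 2
    connectivity: str = "inplane8"

    def __post_init__(self) -> None:
        if self.mode not in ("fraction", "absolute"):
            raise ValueError(f"mode must be 'fraction' or 'absolute', got {self.mode}")
        if self.min_region_voxels < 1:
            raise ValueError("min_region_voxels must be >= 1")

    def absolute_lower(self, vol: PetVolume) -> float:
        if self.mode == "fraction":
            return self.lower * vol.suv_max
        return self.lower


@dataclass
class IUR:
    """A detected connected high-uptake region."""

    voxel_ids: np.ndarray  # (n, 3) int array of voxel indices
    suv_max: float
    bbox: tuple[tuple[int, int], ...]  # inclusive (lo, hi) per axis

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxel_ids.T)] = True
        return m


@dataclass
class SeedSet:
    """Foreground/background seed voxels feeding the random walker."""

    foreground: np.ndarray  # (n, 3) int
    background: np.ndarray  # (m, 3) int
    n_divisor: float = 2.5

    def __post_init__(self) -> None:
        fg = {tuple(v) for v in np.atleast_2d(self.foreground)}
        bg = {tuple(v) for v in np.atleast_2d(self.background)}
        if fg & bg:
            raise ValueError("foreground and background seeds overlap")


def detect_iurs(vol: PetVolume, cfg: EncoderConfig | None = None) -> list[IUR]:
    """Detect interesting uptake regions by threshold-interval encoding.

    Returns IURs sorted by descending SUV_max. An empty list (no voxel in
    the interval, or all components below the size floor) is not an error.
    """
    cfg = cfg or EncoderConfig()
    lower = cfg.absolute_lower(vol)
    if lower >= cfg.upper:
        raise ValueError(f"lower threshold {lower} must be < upper {cfg.upper}")
    inside = (vol.values >= lower) & (vol.values <= cfg.upper)
    if not inside.any():
        return []
    structure = connectivity_structure(cfg.connectivity)
    labels, n = ndimage.label(inside, structure=structure)
    regions: list[IUR] = []
    slices = ndimage.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        comp = labels[sl] == k
        n_vox = int(comp.sum())
        if n_vox < cfg.min_region_voxels:
            continue
        idx = np.argwhere(comp)
        idx += np.array([s.start for s in sl])
        suv_max = float(vol.values[tuple(idx.T)].max())
        bbox = tuple((int(s.start), int(s.stop - 1)) for s in sl)
        regions.append(IUR(voxel_ids=idx, suv_max=suv_max, bbox=bbox))
    regions.sort(key=lambda r: -r.suv_max)
    return regions


def place_seeds(
    vol: PetVolume,
    region: IUR,
    n_divisor: float = 2.5,
    max_radius: int = 15,
    suv_max_rtol: float = 1e-6,
    fg_quantile: float | None = None,
    connectivity: str = "inplane8",
) -> SeedSet:
    """Place foreground/background seeds for one IUR.

    Foreground: region voxels at the region SUV_max (relative tolerance
    ``suv_max_rtol``). On noisy images the exact maximum is a single
    voxel, which starves the random walker of foreground evidence;
    ``fg_quantile`` (e.g. 0.9) instead marks the region's top SUV
    quantile as foreground. Background: breadth-first rings expanding
    outward from the region; the first ring containing voxels with
    SUV <= SUV_max / n_divisor supplies them. Expansion stops after
    ``max_radius`` rings so distant structures are never marked.
    """
    if n_divisor <= 1:
        raise ValueError("n_divisor must be > 1")
    suv = vol.values
    region_mask = region.mask(vol.shape)
    region_suv = suv[tuple(region.voxel_ids.T)]
    if fg_quantile is not None:
        cut = min(np.quantile(region_suv, fg_quantile),
                  region.suv_max * (1.0 - suv_max_rtol))
        fg_sel = region_suv >= cut
    else:
        fg_sel = region_suv >= region.suv_max * (1.0 - suv_max_rtol)
    foreground = region.voxel_ids[fg_sel]
    threshold = region.suv_max / n_divisor
    structure = connectivity_structure(connectivity)

    # ring growth only ever needs the region's neighborhood
    lo = np.maximum(region.voxel_ids.min(axis=0) - max_radius - 1, 0)
    hi = np.minimum(region.voxel_ids.max(axis=0) + max_radius + 2,
                    np.array(vol.shape))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub_suv = suv[box]

    current = region_mask[box]
    background = None
    for _ in range(max_radius):
        grown = ndimage.binary_dilation(current, structure=structure)
        ring = grown & ~current
        if not ring.any():
            break  # region already fills the volume
        qualifying = ring & (sub_suv <= threshold)
        if qualifying.any():
            background = np.argwhere(qualifying) + lo
            break
        current = grown
    if background is None:
        raise SeedingError(
            f"no background voxel with SUV <= {threshold:.3g} within "
            f"{max_radius} rings of the region with SUV_max {region.suv_max:.3g}"
        )
    return SeedSet(foreground=foreground, background=background,
                   n_divisor=n_divisor)
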