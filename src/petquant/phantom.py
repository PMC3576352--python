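"""Seeded synthetic PET phantoms emulating clinical FDG-PET uptake scans.

A phantom is a 3D SUV volume at 4 mm isotropic voxels containing blob-like
lesions (spheres, ellipsoids, or lobulated unions of spheres) with peak SUVs
in the clinical 1-14 range over a low-SUV background, with textured
interiors, Gaussian partial-volume blur (PSF sigma = 1 voxel) and additive
Gaussian noise. Ground-truth masks are the pre-noise lesion supports at
50 % of each lesion's peak contrast, so every downstream stage can be tested
against a known answer.

:func:`generate_cohort` builds paired baseline/follow-up scans with drawn
volume-change and elongation-change factors, mirroring a longitudinal
lesion-tracking study design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import PetVolume

log = logging.getLogger(__name__)


@dataclass
class LesionSpec:
    """Geometry, uptake and texture of one synthetic lesion.

    Physical quantities are in millimetres. ``axis_ratios`` scale the base
    radius per axis (ellipsoids); ``lobes`` is a list of (offset_mm,
    radius_mm) spheres unioned with the main sphere (lobulated shapes).
    """

    shape: str                      # 'sphere' | 'ellipsoid' | 'lobulated'
    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lobes: tuple = ()               # ((dx,dy,dz) mm, radius_mm) pairs
    texture: str = "gaussian-field"  # 'constant' | 'gaussian-field' | 'periodic'
    texture_amp: float = 0.15
    texture_period_mm: float = 28.0
    texture_seed: int = 0


@dataclass
class PhantomSpec:
    """Full synthetic-scan specification."""

    grid_shape: tuple[int, int, int] = (96, 96, 44)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesions: tuple[LesionSpec, ...] = ()
    background_suv: float = 0.8
    noise_sd: float = 0.5
    psf_sigma_voxels: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for les in self.lesions:
            if les.peak_suv <= self.background_suv:
                raise ValueError("lesion peak SUV must exceed the background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _coordinate_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _lesion_support(les: LesionSpec, grids) -> np.ndarray:
    gx, gy, gz = grids
    cx, cy, cz = les.center_mm
    radii = np.array(les.axis_ratios) * les.radius_mm
    support = ((gx - cx) ** 2 / radii[0] ** 2
               + (gy - cy) ** 2 / radii[1] ** 2
               + (gz - cz) ** 2 / radii[2] ** 2) <= 1.0
    if les.shape == "lobulated":
        for (dx, dy, dz), r in les.lobes:
            support |= ((gx - cx - dx) ** 2 + (gy - cy - dy) ** 2
                        + (gz - cz - dz) ** 2) <= r ** 2
    return support


def _texture_profile(les: LesionSpec, support: np.ndarray, grids,
                     spacing) -> np.ndarray:
    """Multiplicative interior modulation in (0, 1], max 1 on the support."""
    if les.texture == "constant" or les.texture_amp <= 0:
        return np.ones_like(support, dtype=float)
    if les.texture == "gaussian-field":
        rng = np.random.default_rng(les.texture_seed)
        u = ndimage.gaussian_filter(rng.standard_normal(support.shape), 1.5)
        vals = u[support]
        span = vals.max() - vals.min()
        norm = (u - vals.min()) / span if span > 0 else np.zeros_like(u)
        return 1.0 - les.texture_amp * np.clip(norm, 0.0, 1.0)
    if les.texture == "periodic":
        gx, gy, _ = grids
        w = 2 * np.pi / les.texture_period_mm
        m = 0.5 + 0.25 * (np.sin(w * gx) + np.sin(w * gy))
        return 1.0 - les.texture_amp * m
    raise ValueError(f"unknown texture model {les.texture!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, list[np.ndarray]]:
    """Render a phantom volume and its ground-truth lesion masks.

    Each lesion's contribution (contrast above background, textured, PSF
    blurred) is rendered separately; its truth mask is the voxels at or
    above 50 % of the lesion's pre-noise peak contrast. Contributions are
    summed onto the background and Gaussian noise is added last (from a
    noise stream independent of the structural seed, so truth masks do
    not depend on the noise draw). Overlapping lesion supports raise an
    error to keep the ground truth unambiguous.
    """
    grids = _coordinate_grids(spec.grid_shape, spec.spacing)
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    volume = np.full(spec.grid_shape, spec.background_suv, dtype=float)
    truths: list[np.ndarray] = []
    for k, les in enumerate(spec.lesions):
        support = _lesion_support(les, grids)
        if not support.any():
            raise ValueError(f"lesion {k} support is empty (outside grid?)")
        edge = np.zeros_like(support)
        edge[0], edge[-1] = True, True
        edge[:, 0], edge[:, -1] = True, True
        edge[:, :, 0], edge[:, :, -1] = True, True
        if (support & edge).any():
            raise ValueError(f"lesion {k} touches the grid border")
        if (support & occupied).any():
            raise ValueError(f"lesion {k} overlaps a previous lesion")
        occupied |= support
        contrast = les.peak_suv - spec.background_suv
        profile = _texture_profile(les, support, grids, spec.spacing)
        contrib = np.where(support, contrast * profile, 0.0)
        if spec.psf_sigma_voxels > 0:
            sigma = [spec.psf_sigma_voxels] * 3  # isotropic in voxel units
            contrib = ndimage.gaussian_filter(contrib, sigma)
        truths.append(contrib >= 0.5 * contrib.max())
        volume += contrib
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([np.uint32(spec.seed), 0xA5A5])
        volume = volume + noise_rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    volume = np.clip(volume, 0.0, None)
    return PetVolume(volume, spacing=spec.spacing), truths


# ----------------------------------------------------------------- cohort

@dataclass
class PatientPhantom:
    """Paired baseline/follow-up phantom specs with drawn true changes."""

    patient_id: int
    baseline: PhantomSpec
    followup: PhantomSpec
    volume_factors: tuple[float, ...]
    elongation_factors: tuple[float, ...]


def _draw_lesions(rng, spec_shape, spacing, n_lesions, peaks, radii_mm,
                  shapes, border_margin_vox=9, min_gap_mm=24.0):
    """Rejection-sample non-overlapping lesion placements."""
    extent = np.array(spec_shape) * np.array(spacing)
    lesions = []
    centers = []
    for peak, r, shape in zip(peaks, radii_mm, shapes):
        ratios = (1.0, 1.0, 1.0)
        lobes = ()
        if shape == "ellipsoid":
            ratios = (1.0, float(rng.uniform(0.7, 1.0)),
                      float(rng.uniform(0.7, 1.0)))
        elif shape == "lobulated":
            n_lobes = int(rng.integers(1, 3))
            lobe_list = []
            for _ in range(n_lobes):
                d = rng.uniform(-1.0, 1.0, 3)
                d /= max(np.linalg.norm(d), 1e-9)
                lobe_list.append((tuple(float(v) for v in d * 0.7 * r),
                                  float(rng.uniform(0.55, 0.75) * r)))
            lobes = tuple(lobe_list)
        reach = max(r * max(ratios),
                    max((np.linalg.norm(off) + lr for off, lr in lobes),
                        default=0.0))
        margin = border_margin_vox * np.array(spacing) + reach
        for _ in range(200):
            c = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm(c - np.array(c2)) >= reach + reach2 + min_gap_mm
                   for c2, reach2 in centers):
                break
        else:
            raise RuntimeError("could not place lesions without overlap")
        centers.append((tuple(c), reach))
        lesions.append(LesionSpec(
            shape=shape, center_mm=tuple(float(v) for v in c),
            radius_mm=float(r), peak_suv=float(peak), axis_ratios=ratios,
            lobes=lobes, texture="gaussian-field", texture_amp=0.15,
            texture_seed=int(rng.integers(2 ** 31)),
        ))
    return lesions


def generate_cohort(
    n_patients: int = 30,
    seed: int = 0,
    grid_shape=(96, 96, 44),
    spacing=(4.0, 4.0, 4.0),
    background_suv: float = 0.8,
    noise_sd: float = 0.5,
    peak_suv_range=(2.0, 14.0),
    radius_range_mm=(12.0, 24.0),
    max_lesions: int = 3,
) -> list[PatientPhantom]:
    """Longitudinal phantom cohort with known morphological changes.

    Each patient gets 1..max_lesions lesions; the hottest lesion's peak SUV
    spans ``peak_suv_range`` across the cohort, and companion lesions draw
    peaks within 60-100 % of it (tracked lesions of comparable avidity, so
    a fraction-of-global-max detector sees each one). Follow-up scans
    rescale each lesion's radius by a drawn volume factor (lognormal,
    clipped to [0.45, 2.2]) and perturb ellipsoid axis ratios (elongation
    change); the drawn factors are recorded per lesion.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    cohort: list[PatientPhantom] = []
    for pid in range(1, n_patients + 1):
        rng = np.random.default_rng([np.uint32(seed), np.uint32(pid)])
        n_lesions = int(rng.integers(1, max_lesions + 1))
        hottest = float(rng.uniform(*peak_suv_range))
        peaks = [hottest] + [hottest * float(rng.uniform(0.6, 1.0))
                             for _ in range(n_lesions - 1)]
        peaks = [max(p, background_suv + 0.5) for p in peaks]
        radii = [float(rng.uniform(*radius_range_mm)) for _ in range(n_lesions)]
        shapes = list(rng.choice(["sphere", "ellipsoid", "lobulated"],
                                 size=n_lesions))
        lesions = _draw_lesions(rng, grid_shape, spacing, n_lesions, peaks,
                                radii, shapes)
        base = PhantomSpec(grid_shape=grid_shape, spacing=spacing,
                           lesions=tuple(lesions),
                           background_suv=background_suv, noise_sd=noise_sd,
                           seed=int(rng.integers(2 ** 31)))

        vol_factors = np.clip(np.exp(rng.normal(0.0, 0.3, n_lesions)),
                              0.45, 2.2)
        elong = rng.uniform(0.85, 1.15, n_lesions)
        fu_lesions = []
        for les, f, e in zip(lesions, vol_factors, elong):
            scale = float(f) ** (1.0 / 3.0)
            ratios = np.array(les.axis_ratios, dtype=float)
            ratios[1] = min(max(ratios[1] * float(e), 0.6), 1.4)
            lobes = tuple((off, r * scale) for off, r in les.lobes)
            fu_lesions.append(replace(
                les, radius_mm=les.radius_mm * scale,
                axis_ratios=tuple(ratios), lobes=lobes,
                peak_suv=float(np.clip(
                    les.peak_suv * rng.uniform(0.8, 1.25),
                    background_suv + 0.5, 15.0)),
                texture_seed=int(rng.integers(2 ** 31)),
            ))
        followup = replace(base, lesions=tuple(fu_lesions),
                           seed=int(rng.integers(2 ** 31)))
        cohort.append(PatientPhantom(
            patient_id=pid, baseline=base, followup=followup,
            volume_factors=tuple(float(f) for f in vol_factors),
            elongation_factors=tuple(float(e) for e in elong),
        ))
    return cohort


def cohort_truth_table(cohort: list[PatientPhantom]) -> pd.DataFrame:
    """Per-lesion bookkeeping of the drawn longitudinal changes."""
    rows = []
    for case in cohort:
        for k, les in enumerate(case.baseline.lesions):
            rows.append({
                "patient": case.patient_id, "lesion": k + 1,
                "shape": les.shape, "peak_suv": les.peak_suv,
                "radius_mm": les.radius_mm,
                "volume_factor": case.volume_factors[k],
                "elongation_factor": case.elongation_factors[k],
            })
    return pd.DataFrame(rows)
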