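"""Core PET volume data model, SUV calibration, and NIfTI I/O.

A :class:`PetVolume` is the substrate of every downstream stage: a 3D grid of
standardized uptake values (SUV, unitless, body-weight normalized) with its
physical voxel spacing in millimetres. Volumes can be loaded from NIfTI files
that already contain SUVs, or produced from activity-concentration images via
:func:`intensity_to_suv` with a dose/weight calibration record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: Physical half-life of 18F in seconds.
F18_HALF_LIFE_S = 6586.2


class VolumeFormatError(ValueError):
    """Raised when an input image violates the 3D-PET-volume contract."""


class CalibrationError(ValueError):
    """Raised for invalid SUV calibration records."""


@dataclass
class PetVolume:
    """3D SUV image with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV per voxel; finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm, all strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise VolumeFormatError(
                f"PET volume must be 3D, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("PET volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")
        if np.any(self.values < 0):
            # negative reconstruction artifacts: clip, uptake is non-negative
            log.warning(
                "clipping %d negative voxels to 0", int(np.sum(self.values < 0))
            )
            self.values = np.clip(self.values, 0.0, None)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def suv_max(self) -> float:
        return float(self.values.max())

    def copy(self) -> "PetVolume":
        return PetVolume(self.values.copy(), self.spacing, self.origin, self.frame)


@dataclass
class SuvCalibration:
    """Dose/weight record converting activity concentration to body-weight SUV.

    SUV = activity [Bq/mL] x body_weight [g] / decay-corrected dose [Bq],
    with the injected dose decayed over ``injection_to_scan_interval_s``.
    """

    injected_dose_bq: float
    body_weight_g: float
    injection_to_scan_interval_s: float = 0.0
    isotope_half_life_s: float = F18_HALF_LIFE_S

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise CalibrationError("injected dose must be > 0 Bq")
        if self.body_weight_g <= 0:
            raise CalibrationError("body weight must be > 0 g")
        if self.injection_to_scan_interval_s < 0:
            raise CalibrationError("injection-to-scan interval must be >= 0 s")
        if self.isotope_half_life_s <= 0:
            raise CalibrationError("half-life must be > 0 s")

    @property
    def decay_corrected_dose_bq(self) -> float:
        decay = 2.0 ** (-self.injection_to_scan_interval_s / self.isotope_half_life_s)
        return self.injected_dose_bq * decay

    @classmethod
    def from_dict(cls, d: dict) -> "SuvCalibration":
        """Build from a {dose_bq, weight_g, interval_s, half_life_s} mapping."""
        return cls(
            injected_dose_bq=float(d["dose_bq"]),
            body_weight_g=float(d["weight_g"]),
            injection_to_scan_interval_s=float(d.get("interval_s", 0.0)),
            isotope_half_life_s=float(d.get("half_life_s", F18_HALF_LIFE_S)),
        )


def intensity_to_suv(activity_bq_ml: np.ndarray, cal: SuvCalibration,
                     spacing=(4.0, 4.0, 4.0), origin=(0.0, 0.0, 0.0)) -> PetVolume:
    """Convert an activity-concentration grid (Bq/mL) to a SUV volume.

    Body-weight SUV with decay correction of the injected dose to scan start:
    ``SUV = activity * weight / (dose * 2**(-interval / half_life))``.
    Linear in activity for a fixed calibration.
    """
    activity = np.asarray(activity_bq_ml, dtype=np.float64)
    if not np.all(np.isfinite(activity)):
        raise VolumeFormatError("activity grid contains non-finite values")
    suv = activity * cal.body_weight_g / cal.decay_corrected_dose_bq
    return PetVolume(suv, spacing=spacing, origin=origin)


def load_pet_volume(path) -> PetVolume:
    """Load a 3D SUV NIfTI image as a :class:`PetVolume`.

    Spacing comes from the header zooms; values are cast to float. Raises
    :class:`VolumeFormatError` for non-3D images or non-positive spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return PetVolume(data.astype(np.float64), spacing=tuple(map(float, zooms)),
                     origin=origin)


def save_pet_volume(vol: PetVolume, path) -> None:
    """Write a volume (float32) as NIfTI with a diagonal affine from spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, spacing, path, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a binary (or small-integer label) mask as uint8 NIfTI."""
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI mask; returns (integer array, spacing)."""
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D mask, got {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data.astype(np.int32), zooms


def load_calibration(path) -> SuvCalibration:
    """Read a calibration record from a YAML or JSON file.

    Expected keys: ``dose_bq``, ``weight_g`` and optionally ``interval_s``,
    ``half_life_s``.
    """
    import json

    import yaml

    text = open(path).read()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    return SuvCalibration.from_dict(data)
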