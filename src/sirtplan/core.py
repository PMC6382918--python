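"""Core data model and preprocessing for the SIRT planning pipeline.

The pipeline moves 3D scalar volumes between several modalities acquired
before radioembolization: the low-dose CT of the ⁹⁹ᵐTc-MAA SPECT/CT study
(``CT_MAA``), the contrast-enhanced CT and FDG-PET of the ¹⁸F-FDG PET/CT
study (``CT_FDG``/``PET_FDG``), and per-lobe contrast-enhanced cone-beam CTs
(``CBCT``).  Everything downstream (registration, segmentation, dosimetry)
works on the :class:`Volume` / :class:`Mask` carriers defined here.

Geometry conventions
--------------------
* Arrays are indexed ``(x, y, z)`` with ``z`` the axial slice index.
* Voxel indices are 0-based; crop boxes are half-open ``[lo, hi)``.
* World coordinates (mm) are axis-aligned: ``world = origin + index * spacing``.
  Oblique affines are deliberately out of scope; the phantom geometry and the
  clinical crop-box workflow need no rotation of the grid itself.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class Modality(Enum):
    """Acquisition the volume came from."""

    CT_MAA = "CT_MAA"
    CT_FDG = "CT_FDG"
    PET_FDG = "PET_FDG"
    CBCT = "CBCT"
    OTHER = "OTHER"


@dataclass
class Volume:
    """A 3D scalar image with axis-aligned geometry.

    Parameters
    ----------
    data
        3D array; HU for CT/CBCT, kBq/cc or SUV for PET.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    modality
        Which acquisition this carries; used only for bookkeeping.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"all axes must have length >= 2, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (mm³ / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "Volume":
        return Volume(data, self.spacing, self.origin, modality or self.modality)


@dataclass
class Mask:
    """Binary volume-of-interest on a reference :class:`Volume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Mask data must be 3D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("Mask values must be in {0, 1}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cc(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_cc

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return Volume.same_grid(self, other, atol)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray, label: str | None = None) -> "Mask":
        return Mask(data, self.spacing, self.origin, self.label if label is None else label)

    @classmethod
    def like(cls, vol: "Volume | Mask", data: np.ndarray, label: str = "") -> "Mask":
        return cls(data, vol.spacing, vol.origin, label)


@dataclass(frozen=True)
class CropBox:
    """Per-axis half-open index ranges ``[lo, hi)`` bounding the liver."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("CropBox needs 3 lo and 3 hi indices")
        for lo, hi in zip(self.lo, self.hi):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid box extent [{lo}, {hi})")

    def validate_for(self, shape: Sequence[int]) -> None:
        for ax, (hi, n) in enumerate(zip(self.hi, shape)):
            if hi > n:
                raise ValueError(f"box exceeds axis {ax}: hi={hi} > {n}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lo, self.hi))

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lo, self.hi))


@dataclass(frozen=True)
class SuvParams:
    """Inputs of the body-weight SUV normalisation.

    ``injected_activity`` is the activity at injection time (MBq);
    ``injection_to_scan`` the uptake interval in minutes; ``half_life`` the
    isotope half-life in minutes (¹⁸F: 109.77); ``body_weight`` in kg.
    """

    injected_activity: float
    injection_to_scan: float
    half_life: float = 109.77
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        for name in ("injected_activity", "injection_to_scan", "half_life", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def decay_corrected_activity_mbq(self) -> float:
        """Activity remaining at scan time (MBq)."""
        return self.injected_activity * 2.0 ** (-self.injection_to_scan / self.half_life)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume | Mask, path: str | os.PathLike) -> str:
    """Write a volume or mask as NIfTI-1 (.nii / .nii.gz)."""
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return str(path)


def read_volume(path: str | os.PathLike, modality: Modality = Modality.OTHER) -> Volume:
    """Read a 3D NIfTI-1 file into a :class:`Volume`.

    Only axis-aligned affines are supported; spacing is taken from the header
    zooms and the origin from the affine translation.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D NIfTI, got ndim={data.ndim} in {path}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return Volume(np.ascontiguousarray(data), tuple(zooms), tuple(origin), modality)


def read_mask(path: str | os.PathLike, label: str = "") -> Mask:
    vol = read_volume(path)
    return Mask(vol.data > 0.5, vol.spacing, vol.origin, label)


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop(volume: Volume | Mask, box: CropBox):
    """Crop to the box; the origin shifts by ``lo * spacing`` so world
    coordinates of retained voxels are unchanged."""
    box.validate_for(volume.shape)
    new_origin = tuple(o + lo * s for o, lo, s in zip(volume.origin, box.lo, volume.spacing))
    data = volume.data[box.slices].copy()
    if isinstance(volume, Mask):
        return Mask(data, volume.spacing, new_origin, volume.label)
    return Volume(data, volume.spacing, new_origin, volume.modality)


def uncrop(volume: Volume, box: CropBox, full_shape: Sequence[int], fill: float = 0.0) -> Volume:
    """Pad a cropped volume back into the full grid (inverse of :func:`crop`)."""
    box.validate_for(full_shape)
    if tuple(box.extents) != tuple(volume.shape):
        raise ValueError("volume shape does not match box extents")
    out = np.full(tuple(full_shape), fill, dtype=volume.data.dtype)
    out[box.slices] = volume.data
    orig = tuple(o - lo * s for o, lo, s in zip(volume.origin, box.lo, volume.spacing))
    return Volume(out, volume.spacing, orig, volume.modality)


# ---------------------------------------------------------------------------
# Median preprocessing
# ---------------------------------------------------------------------------

# One "triple" = a 3x3 in-plane median applied slice-wise in each orthogonal
# orientation in turn (axial -> coronal -> sagittal).  With arrays indexed
# (x, y, z), an axial slice is data[:, :, k], so the axial pass filters in
# (x, y), the coronal pass in (x, z) and the sagittal pass in (y, z).
_ORIENTATION_SIZES = ((3, 3, 1), (3, 1, 3), (1, 3, 3))


def median_filter_stack(volume: Volume, passes: int = 3) -> Volume:
    """Edge-preserving noise suppression for CT/CBCT volumes.

    Each pass applies a 3×3 2D median slice-wise along each of the three
    orthogonal orientations in a fixed order; the triple is repeated
    ``passes`` times (default 3).  Borders are handled by nearest replication.
    Used only to stabilise registration and segmentation decisions — reported
    quantities are always taken from the unsmoothed volumes.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    data = np.asarray(volume.data, dtype=float)
    for _ in range(passes):
        for size in _ORIENTATION_SIZES:
            data = ndimage.median_filter(data, size=size, mode="nearest")
    return volume.with_data(data)


# ---------------------------------------------------------------------------
# Metric (mm) morphology
# ---------------------------------------------------------------------------
# Structuring elements are true mm balls realised through the Euclidean
# distance transform with the grid spacing as sampling, so anisotropic voxels
# (e.g. 2.9 x 2.9 x 5 mm PET) behave correctly.

def dilate_mm(data: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Binary dilation with a metric ball of ``radius_mm``."""
    if not data.any():
        return data.copy()
    dist = ndimage.distance_transform_edt(~data, sampling=spacing)
    return dist <= radius_mm + 1e-9


def erode_mm(data: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Binary erosion with a metric ball of ``radius_mm`` (closed ball: a
    background voxel at exactly ``radius_mm`` removes the voxel, mirroring
    the dilation convention)."""
    dist = ndimage.distance_transform_edt(data, sampling=spacing)
    return dist > radius_mm + 1e-9


def close_mm(data: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    return erode_mm(dilate_mm(data, radius_mm, spacing), radius_mm, spacing)


def open_mm(data: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    return dilate_mm(erode_mm(data, radius_mm, spacing), radius_mm, spacing)


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def to_suv(pet_volume: Volume, params: SuvParams) -> Volume:
    """Convert a PET activity-concentration image (kBq/cc) to body-weight SUV.

    SUV = concentration / (decay-corrected injected activity / body weight),
    with tissue density taken as 1 g/cc so that cc and g are interchangeable.
    A voxel whose concentration equals the decay-corrected injected activity
    per gram of body weight therefore maps to SUV 1.
    """
    if np.any(pet_volume.data < 0):
        raise ValueError("PET concentration must be nonnegative")
    act_kbq = params.decay_corrected_activity_mbq * 1000.0
    weight_g = params.body_weight * 1000.0
    suv = pet_volume.data * (weight_g / act_kbq)
    return pet_volume.with_data(suv)
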