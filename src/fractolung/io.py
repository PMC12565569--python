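"""CT volumes, binary masks, and the normal-attenuation-area (NAA) window.

Conventions
-----------
* Voxel indices are 0-based; array axes are ordered (x, y, z) with x fastest.
* World coordinates (mm) = index * spacing; no origin/orientation transforms
  are applied beyond axis ordering.
* Lung segmentation masks are consumed, never produced: segmentation is an
  upstream step.

The NAA mask is the binary set on which all fractal metrics are computed:
lung voxels whose attenuation lies in the window (-950, -700] HU, i.e.
parenchyma that is neither emphysematous/air-like (<= -950 HU) nor
consolidated (> -700 HU).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from fractolung.errors import ConfigurationError, GeometryError, VolumeReadError

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GeometryError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A scalar Hounsfield-unit grid with physical voxel spacing.

    Attributes
    ----------
    hu : 3D float array of Hounsfield units, axes (x, y, z).
    spacing : (x, y, z) voxel edge lengths in mm, each > 0.
    orientation : axis-order tag (informational; data are already in xyz order).
    """

    hu: np.ndarray
    spacing: Spacing
    orientation: str = "xyz"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise GeometryError(f"HU grid must be 3D, got shape {self.hu.shape}")
        if not np.all(np.isfinite(self.hu)):
            raise VolumeReadError("HU grid contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape


@dataclass
class BinaryMask3D:
    """A voxel occupancy grid sharing a CT volume's geometry."""

    occupancy: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.occupancy.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    def coordinates_mm(self) -> np.ndarray:
        """Physical (mm) coordinates of occupied voxels, shape (n, 3)."""
        idx = np.argwhere(self.occupancy).astype(float)
        return idx * np.asarray(self.spacing)

    def volume_mm3(self) -> float:
        return self.n_occupied * float(np.prod(self.spacing))

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.occupancy.copy(), self.spacing)


@dataclass(frozen=True)
class NAAWindow:
    """Attenuation window defining normal attenuation areas.

    A voxel belongs to the NAA iff ``lower_hu < HU <= upper_hu``; the lower
    bound is exclusive and the upper bound inclusive.
    """

    lower_hu: float = -950.0
    upper_hu: float = -700.0

    def __post_init__(self) -> None:
        if not self.lower_hu < self.upper_hu:
            raise ConfigurationError(
                f"NAA window requires lower_hu < upper_hu, got "
                f"({self.lower_hu}, {self.upper_hu})"
            )


def make_naa_mask(
    ct: CTVolume, lung: BinaryMask3D, window: NAAWindow = NAAWindow()
) -> BinaryMask3D:
    """Binary mask of lung voxels within the NAA attenuation window.

    A voxel is included iff it lies inside the lung mask AND
    ``window.lower_hu < HU <= window.upper_hu`` (lower-exclusive,
    upper-inclusive).
    """
    if ct.shape != lung.shape:
        raise GeometryError(
            f"CT shape {ct.shape} does not match lung mask shape {lung.shape}"
        )
    inside = (ct.hu > window.lower_hu) & (ct.hu <= window.upper_hu)
    return BinaryMask3D(lung.occupancy & inside, ct.spacing)


def resample_isotropic(mask: BinaryMask3D, target_mm: float = 1.0) -> BinaryMask3D:
    """Nearest-neighbour resampling of a mask to isotropic voxels.

    Box-counting and gliding-box statistics assume cubic cells; anisotropic
    masks (e.g. 1.0 x 1.0 x 2.5 mm CT) are resampled before those metrics.
    Occupied physical volume is preserved to within a few percent on smooth
    shapes.
    """
    if target_mm <= 0:
        raise ConfigurationError(f"target_mm must be > 0, got {target_mm}")
    if all(abs(s - target_mm) < 1e-12 for s in mask.spacing):
        return mask.copy()
    if mask.n_occupied == 0:
        shape = tuple(
            max(1, int(round(d * s / target_mm)))
            for d, s in zip(mask.shape, mask.spacing)
        )
        return BinaryMask3D(np.zeros(shape, dtype=bool), (target_mm,) * 3)
    zoom = tuple(s / target_mm for s in mask.spacing)
    out = ndimage.zoom(mask.occupancy.astype(np.uint8), zoom, order=0, grid_mode=True,
                       mode="grid-constant")
    return BinaryMask3D(out > 0, (target_mm,) * 3)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: Spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(ct: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI with a diagonal (spacing-only) affine."""
    img = nib.Nifti1Image(ct.hu.astype(np.float32), _nifti_affine(ct.spacing))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask3D, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI with 0/1 voxels."""
    img = nib.Nifti1Image(
        mask.occupancy.astype(np.uint8), _nifti_affine(mask.spacing)
    )
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, Spacing]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeReadError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=float), spacing


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, Spacing]:
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in {".dcm", ""}
    )
    if not files:
        raise VolumeReadError(f"no DICOM files found in {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise VolumeReadError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append(ds)
    modality = getattr(slices[0], "Modality", None)
    if modality is not None and modality != "CT":
        raise VolumeReadError(f"series modality is {modality!r}, expected CT")
    slices.sort(key=lambda ds: int(ds.InstanceNumber))
    numbers = [int(ds.InstanceNumber) for ds in slices]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        gaps = sorted(set(expected) - set(numbers))
        raise VolumeReadError(
            f"DICOM series has missing/duplicated instance numbers; gaps at {gaps}"
        )
    pixel_spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in slices}
    if len(pixel_spacings) != 1:
        raise VolumeReadError(
            f"inconsistent in-plane PixelSpacing across slices: {sorted(pixel_spacings)}"
        )
    row_mm, col_mm = pixel_spacings.pop()  # (row=y, col=x) per DICOM
    if len(slices) > 1 and all(hasattr(ds, "ImagePositionPatient") for ds in slices):
        zs = [float(ds.ImagePositionPatient[2]) for ds in slices]
        dz = np.diff(sorted(zs))
        if dz.size and (dz.max() - dz.min()) > 1e-3 * max(dz.max(), 1.0):
            raise VolumeReadError(
                f"inconsistent slice spacing: {dz.min():.4f}..{dz.max():.4f} mm"
            )
        slice_mm = float(np.mean(np.abs(dz))) if dz.size else float(
            getattr(slices[0], "SliceThickness", 1.0)
        )
    else:
        slice_mm = float(getattr(slices[0], "SliceThickness", 1.0))
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    vol_zyx = np.stack(planes, axis=0)  # (z, y, x)
    hu = np.transpose(vol_zyx, (2, 1, 0))  # -> (x, y, z)
    return hu, (float(col_mm), float(row_mm), slice_mm)


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : NIfTI file (.nii / .nii.gz) or a directory of CT DICOM slices.
    format : 'nifti' or 'dicom'; inferred from the path when omitted.

    DICOM rescale slope/intercept are applied so values are Hounsfield units;
    instance-number gaps, inconsistent spacings and non-CT modalities raise
    :class:`VolumeReadError`.
    """
    p = Path(path)
    if format is None:
        format = "dicom" if p.is_dir() else "nifti"
    if format == "nifti":
        data, spacing = _read_nifti(p)
        return CTVolume(data, spacing)
    if format == "dicom":
        if not p.is_dir():
            raise VolumeReadError(f"DICOM format expects a series directory, got {p}")
        hu, spacing = _read_dicom_series(p)
        return CTVolume(hu, spacing)
    raise ConfigurationError(f"unknown volume format {format!r}")


def read_mask(path: str | os.PathLike) -> BinaryMask3D:
    """Read a binary mask from NIfTI; voxels > 0.5 are occupied."""
    data, spacing = _read_nifti(Path(path))
    return BinaryMask3D(data > 0.5, spacing)
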