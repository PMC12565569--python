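"""Shared helpers: brute-force oracles and a minimal DICOM series writer."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid


def brute_force_box_counts(occ: np.ndarray, scales) -> list[int]:
    """Literal triple-loop box counting, grid anchored at the array corner."""
    occ = np.asarray(occ, dtype=bool)
    out = []
    for s in scales:
        count = 0
        for i in range(0, occ.shape[0], s):
            for j in range(0, occ.shape[1], s):
                for k in range(0, occ.shape[2], s):
                    if occ[i:i + s, j:j + s, k:k + s].any():
                        count += 1
        out.append(count)
    return out


def brute_force_lacunarity(occ: np.ndarray, r: int) -> float:
    """Literal gliding-box enumeration: Var(M)/Mean(M)^2 over all interior
    r-cube windows (stride 1, population variance)."""
    occ = np.asarray(occ, dtype=float)
    masses = []
    for i in range(occ.shape[0] - r + 1):
        for j in range(occ.shape[1] - r + 1):
            for k in range(occ.shape[2] - r + 1):
                masses.append(occ[i:i + r, j:j + r, k:k + r].sum())
    masses = np.asarray(masses)
    return float(masses.var() / masses.mean() ** 2)


def write_dicom_slice(
    path,
    pixels: np.ndarray,
    instance_number: int,
    z_mm: float,
    pixel_spacing=(0.7, 0.7),
    slice_thickness: float = 2.5,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
    modality: str = "CT",
    series_uid: str | None = None,
) -> None:
    """Write one minimal CT DICOM slice (explicit VR little endian)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(path)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid or generate_uid(entropy_srcs=["series"])
    ds.Modality = modality
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(pixel_spacing[0]), float(pixel_spacing[1])]
    ds.SliceThickness = slice_thickness
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = rescale_slope
    ds.RescaleIntercept = rescale_intercept
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    pydicom.dcmwrite(str(path), ds)


@pytest.fixture
def dicom_series_dir(tmp_path):
    """Three-slice 8x8 CT series; stored value 224 with intercept -1024 is
    -800 HU.  Returns (directory, expected HU volume in (x, y, z) order)."""
    d = tmp_path / "series"
    d.mkdir()
    series_uid = generate_uid(entropy_srcs=["fixture-series"])
    rng = np.random.default_rng(7)
    stored = rng.integers(0, 1200, size=(3, 8, 8)).astype(np.uint16)
    stored[0, 0, 0] = 224  # -> -800 HU
    for i in range(3):
        write_dicom_slice(
            d / f"slice_{i:03d}.dcm", stored[i], instance_number=i + 1,
            z_mm=10.0 + 2.5 * i, series_uid=series_uid,
        )
    hu_zyx = stored.astype(float) - 1024.0
    hu_xyz = np.transpose(hu_zyx, (2, 1, 0))
    return d, hu_xyz
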