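"""Shared fixtures: small synthetic volumes and on-the-fly DICOM writers."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from havdvh import BinaryMask, ImageVolume


@pytest.fixture
def random_ct_and_mask():
    """Factory: (ct, lung_mask) with lung HU spanning the -856 threshold."""

    def make(seed: int, shape=(12, 12, 6), lav_fraction=0.3):
        rng = np.random.default_rng(seed)
        hu = rng.normal(0, 30, size=shape)
        lung = rng.uniform(size=shape) < 0.6
        lung_hu = np.where(rng.uniform(size=shape) < lav_fraction,
                           rng.normal(-920, 20, size=shape),
                           rng.normal(-750, 40, size=shape))
        hu = np.where(lung, lung_hu, hu)
        ct = ImageVolume(hu, spacing=(2.0, 2.0, 3.0))
        return ct, BinaryMask(lung, reference=ct)

    return make


@pytest.fixture
def random_dose():
    """Factory: dose volume on a given geometry, values in [0, 60] Gy."""

    def make(seed: int, geometry: ImageVolume):
        rng = np.random.default_rng(seed)
        return ImageVolume(rng.uniform(0, 60, size=geometry.shape),
                           spacing=geometry.spacing, origin=geometry.origin)

    return make


def _base_dataset(modality: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = generate_uid()
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "PHANTOM"
    return ds


def write_ct_slice(path, pixel_array_xy, z_mm, series_uid, spacing=(1.0, 1.0),
                   slope=1.0, intercept=-1024.0, modality="CT"):
    """Write one synthetic CT slice; pixel_array_xy is (nx, ny) in HU."""
    stored = np.round((pixel_array_xy.T - intercept) / slope).astype(np.int16)
    ds = _base_dataset(modality)
    ds.SeriesInstanceUID = series_uid
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [spacing[1], spacing[0]]  # (row, col) = (dy, dx)
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_ct_series(directory, volume_hu, spacing=(1.0, 1.0, 2.0),
                    slope=1.0, intercept=-1024.0, skip_slices=()):
    """Write a synthetic CT series from an (nx, ny, nz) HU array."""
    directory.mkdir(parents=True, exist_ok=True)
    uid = generate_uid()
    for k in range(volume_hu.shape[2]):
        if k in skip_slices:
            continue
        write_ct_slice(directory / f"slice_{k:03d}.dcm", volume_hu[:, :, k],
                       z_mm=k * spacing[2], series_uid=uid, spacing=spacing[:2],
                       slope=slope, intercept=intercept)
    return directory


def write_rtdose(path, dose_xyz, spacing=(2.0, 2.0, 2.0), scaling=1e-3,
                 origin=(0.0, 0.0, 0.0)):
    """Write a synthetic RTDOSE file from an (nx, ny, nz) Gy array."""
    stored = np.round(dose_xyz / scaling).astype(np.uint32)
    frames = np.transpose(stored, (2, 1, 0))  # (z, y, x)
    ds = _base_dataset("RTDOSE")
    ds.SeriesInstanceUID = generate_uid()
    ds.NumberOfFrames, ds.Rows, ds.Columns = frames.shape
    ds.PixelSpacing = [spacing[1], spacing[0]]
    ds.ImagePositionPatient = list(map(float, origin))
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * spacing[2] for k in range(frames.shape[0])]
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = frames.astype("<u4").tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
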