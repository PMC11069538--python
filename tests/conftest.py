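from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from echohet.image_io import USImage


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240504)


def make_image(arr: np.ndarray, bit_depth: int = 8, source_id: str = "test") -> USImage:
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return USImage(np.asarray(arr, dtype=dtype), bit_depth, source_id)


def write_dicom(
    path,
    pixels: np.ndarray,
    photometric: str = "MONOCHROME2",
    n_frames: int = 1,
) -> None:
    """Write a minimal single/multi-frame secondary-capture DICOM file."""
    pixels = np.asarray(pixels)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PhotometricInterpretation = photometric
    if photometric == "RGB":
        ds.SamplesPerPixel = 3
        ds.PlanarConfiguration = 0
        ds.Rows, ds.Columns = pixels.shape[:2]
    else:
        ds.SamplesPerPixel = 1
        ds.Rows, ds.Columns = pixels.shape[-2:]
    if n_frames > 1:
        ds.NumberOfFrames = n_frames
    ds.BitsAllocated = 8 if pixels.dtype == np.uint8 else 16
    ds.BitsStored = ds.BitsAllocated
    ds.HighBit = ds.BitsAllocated - 1
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


@pytest.fixture
def dicom_writer():
    return write_dicom
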