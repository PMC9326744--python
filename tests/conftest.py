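"""Shared fixtures.

The expensive phantom training run (three tiny networks on a noise-free
cohort) happens once per session; every test that needs trained
checkpoints or held-out predictions consumes the same
:func:`e2e_report` fixture.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from adpkdvol.phantom import PhantomSpec, generate_phantom
from adpkdvol.pipeline import end_to_end_phantom_check


@pytest.fixture(scope="session")
def noise_free_phantom():
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def e2e_report():
    """The full phantom self-check: cohort, split, training, inference."""
    return end_to_end_phantom_check(seed=0, n_subjects=8, max_epochs=30)


def write_dicom_series(
    directory: Path,
    volume: np.ndarray,
    pixel_spacing=(1.25, 1.25),
    slice_gap: float = 5.0,
    series_uid: str | None = None,
    slice_order=None,
    patient_id: str = "TEST001",
) -> Path:
    """Write ``volume`` (rows, cols, slices) as a single-frame axial series."""
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    n_slices = volume.shape[2]
    order = slice_order if slice_order is not None else range(n_slices)
    for file_idx, k in enumerate(order):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.PatientID = patient_id
        ds.Modality = "MR"
        ds.SeriesDescription = "AX T2 SSFSE"
        ds.Rows, ds.Columns = volume.shape[:2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [pixel_spacing[0], pixel_spacing[1]]
        ds.SliceThickness = slice_gap
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]  # axial
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * slice_gap]
        ds.InstanceNumber = k + 1
        ds.PixelData = volume[:, :, k].astype(np.uint16).tobytes()
        ds.save_as(directory / f"slice_{file_idx:03d}.dcm", enforce_file_format=True)
    return directory
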