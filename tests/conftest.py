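from pathlib import Path

import numpy as np
import pydicom
import pytest
from hypothesis import settings
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import petfract as pf

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def write_dicom_series(directory, arr, spacing=(2.0, 2.0, 4.0)):
    """Write one synthetic axial DICOM series, one file per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=["petfract-test"])
    for k in range(arr.shape[2]):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=["petfract-test", str(k)]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "PT"
        ds.Rows, ds.Columns = arr.shape[0], arr.shape[1]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [spacing[0], spacing[1]]
        ds.SliceThickness = spacing[2]
        ds.ImagePositionPatient = [0.0, 0.0, k * spacing[2]]
        ds.InstanceNumber = k + 1
        ds.PixelData = arr[:, :, k].astype(np.uint16).tobytes()
        ds.save_as(directory / f"slice{k:03d}.dcm", enforce_file_format=True)
    return directory


@pytest.fixture
def dicom_writer():
    return write_dicom_series


def random_volume(seed, shape=(16, 16, 16), sparsity=0.5):
    """A seeded random quantized volume with a mix of empty and hot voxels."""
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 256, size=shape).astype(float)
    values[rng.random(shape) < sparsity] = 0.0
    return pf.TracerVolume(values, provenance="phantom", subject_id=f"rand-{seed}")


@pytest.fixture
def make_random_volume():
    return random_volume


@pytest.fixture(scope="session")
def cohort_records():
    return pf.load_fixtures()


@pytest.fixture(scope="session")
def uniform32():
    return pf.generate(pf.PhantomSpec("uniform", level=5))


@pytest.fixture(scope="session")
def cascade_weights():
    return (0.75, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def cascade128(cascade_weights):
    return pf.generate(pf.PhantomSpec("cascade", level=7, weights=cascade_weights))
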