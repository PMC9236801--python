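import numpy as np
import pytest

from adipoct.core import GreyImage
from adipoct.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free default phantom with exact masks."""
    return make_phantom(PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_truth():
    """Default phantom at the standard noise level."""
    return make_phantom(PhantomSpec(noise_sd=0.02, rng_seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, shape=(32, 32), low=0.05, high=1.0):
    """Random grey image with all pixels non-background."""
    return GreyImage(rng.uniform(low, high, size=shape))


def write_test_dicom(path, pixels16, slope=1.0, intercept=0.0):
    """Write a minimal single-frame grey-scale DICOM for round-trip tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels16.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = np.ascontiguousarray(pixels16, dtype=np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
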