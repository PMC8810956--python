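import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from ltpdetect.phantom import PhantomParams, generate_case
from ltpdetect.windowing import compose_channels

SMALL_SHAPE = (96, 96, 32)


def small_params(**overrides) -> PhantomParams:
    """Compact phantom parameters used across the suite."""
    defaults = dict(
        volume_shape=SMALL_SHAPE,
        ablation_radius_mm=10.0,
        lesion_diameter_mm=8.0,
        n_vessels=2,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def phantom_case():
    return generate_case(small_params(), "fx0")


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_case(small_params(liver_hu_noise_sd=0.0), "fx1")


@pytest.fixture(scope="session")
def mcv(phantom_case):
    return compose_channels(phantom_case.volume)


def write_dicom_slice(path, pixels, position, series_uid,
                      slope=1.0, intercept=-1024.0,
                      orientation=(1, 0, 0, 0, 1, 0), spacing=(0.7, 0.7)):
    """Write one synthetic CT slice as a DICOM file."""
    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [spacing[0], spacing[1]]  # (row, col)
    ds.SliceThickness = 3.0
    ds.ImageOrientationPatient = list(orientation)
    ds.ImagePositionPatient = [float(v) for v in position]
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.asarray(pixels, dtype=np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return ds
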