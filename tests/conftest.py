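import numpy as np
import pytest

from erisnet.dicom_io import CTImage, DoseTag, ImagePair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pair(rng):
    """A 32x32 paired slice with mild noise on the LQ arm."""
    hq_px = np.full((32, 32), -1000.0)
    hq_px[8:24, 8:24] = 40.0
    hq = CTImage(hq_px, patient_id="P0", slice_index=0, dose_tag=DoseTag.HQ)
    lq = CTImage(
        hq_px + rng.normal(0, 20.0, hq_px.shape),
        patient_id="P0",
        slice_index=0,
        dose_tag=DoseTag.LQ,
    )
    return ImagePair(hq=hq, lq=lq, dose_fraction=0.5)
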