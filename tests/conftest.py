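import numpy as np
import pytest

from neurocardiac.nuisance import BOLDImage, _default_affine
from neurocardiac.physio import IBISeries, RawSignal


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def regular_ibi():
    """75 beats at exactly 800 ms spacing (60 s recording)."""
    return IBISeries.from_intervals([800.0] * 74)


@pytest.fixture
def small_grid_affine():
    return _default_affine((21, 21, 21), voxel_size=2.5)


def make_bold(data, tr=0.484, **kw):
    return BOLDImage(data=np.asarray(data, dtype=float), tr=tr, **kw)


@pytest.fixture
def sinusoid_resp():
    """Pure 0.25 Hz respiration sinusoid over 60 s at 50 Hz."""
    fs = 50.0
    t = np.arange(int(60 * fs)) / fs
    return RawSignal(samples=np.sin(2 * np.pi * 0.25 * t),
                     sampling_rate=fs, channel="respiration")
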