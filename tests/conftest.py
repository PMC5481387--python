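import numpy as np
import pytest

from bayescluster3d import ROI, LocalizationTable

STANDARD_ROI = ROI(3000.0, 3000.0, 600.0)


@pytest.fixture
def roi():
    return STANDARD_ROI


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(xyz, sigma=10.0):
    """LocalizationTable with constant isotropic precision."""
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    return LocalizationTable(xyz, np.full_like(xyz, float(sigma)))


@pytest.fixture
def csr_table(rng, roi):
    """1000 CSR points in the standard ROI."""
    xyz = rng.uniform(0, 1, (1000, 3)) * roi.lengths
    return make_table(xyz, sigma=20.0)
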