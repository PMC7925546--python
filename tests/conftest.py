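import numpy as np
import pytest

from plaidgamma import ContrastGrid, MatrixGroundTruth, SpectrumGroundTruth
from plaidgamma.synth import default_freq_grid


@pytest.fixture(scope="session")
def grid():
    return ContrastGrid()


@pytest.fixture(scope="session")
def freq_grid():
    return default_freq_grid()


@pytest.fixture(scope="session")
def spectrum_truth():
    """Reference spectrum ground truth: gammas at 50 and 80 Hz."""
    return SpectrumGroundTruth()


@pytest.fixture(scope="session")
def matrix_truth():
    return MatrixGroundTruth(Rmax=1.2, c50=0.2, m1=2.0, m2=1.5, b=0.6,
                             R0=0.05, noise_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
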