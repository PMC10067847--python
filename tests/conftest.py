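import numpy as np
import pytest
from scipy import sparse

from spotmap.io import PeakMatrix
from spotmap.synth import GroundTruthPattern, simulate_pattern


@pytest.fixture
def small_peak_matrix():
    """4 pixels x 3 peaks with a mix of zeros."""
    coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
    mz = np.array([100.0, 200.0, 300.0])
    vals = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 0.0], [4.0, 5.0, 6.0], [0.0, 0.0, 0.5]])
    return PeakMatrix(coords, mz, sparse.csr_matrix(vals))


@pytest.fixture(scope="session")
def ring_truth():
    return GroundTruthPattern("ring")


@pytest.fixture(scope="session")
def ring_sim(ring_truth):
    """One frozen realization of the ring ground-truth pattern."""
    return simulate_pattern(ring_truth, seed=0)


def gaussian_profile(centers, sigmas, heights, lo=395.0, hi=405.0, step=2e-4,
                     baseline=0.0, noise_sd=0.0, seed=0):
    """Synthetic profile spectrum made of Gaussian peaks on a fine m/z grid."""
    rng = np.random.default_rng(seed)
    mz = np.arange(lo, hi, step)
    inten = np.full(mz.size, baseline)
    for c, s, h in zip(centers, sigmas, heights):
        inten = inten + h * np.exp(-((mz - c) ** 2) / (2 * s * s))
    if noise_sd:
        inten = np.abs(inten + rng.normal(0, noise_sd, mz.size))
    return mz, inten
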