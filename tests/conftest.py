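import logging

import numpy as np
import pytest

from lipidfinger.spectra_io import Spectrum

logging.getLogger("lipidfinger").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_spectrum():
    """A uniform-grid spectrum with constant intensity."""
    mz = np.arange(400.0, 500.0, 0.01)
    return Spectrum(mz=mz, intensity=np.full(mz.size, 3.0))


def gaussian_spectrum(centers, heights, lo=400.0, hi=500.0, step=0.01,
                      resolution=10000.0, offset=0.0):
    """Noise-free profile spectrum with Gaussian peaks (test helper)."""
    grid = np.arange(lo, hi + step / 2, step)
    y = np.full(grid.size, float(offset))
    for c, h in zip(centers, heights):
        sigma = c / resolution / 2.3548200450309493
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return Spectrum(mz=grid, intensity=y)


@pytest.fixture()
def gaussian_factory():
    return gaussian_spectrum
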