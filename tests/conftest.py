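import numpy as np
import pytest

from glycomig.glycolib import build_library
from glycomig.spectra import Spectrum


@pytest.fixture(scope="session")
def library():
    return build_library()


def gaussian_spectrum(
    centers,
    heights,
    fwhm=2.5,
    lo=2300.0,
    hi=3600.0,
    step=0.1,
    baseline=None,
    noise_sd=0.0,
    seed=0,
):
    """Sum-of-Gaussians test spectrum with optional baseline and noise."""
    grid = np.arange(lo, hi + step / 2, step)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    if baseline is not None:
        y = y + baseline(grid)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, y)


@pytest.fixture
def make_spectrum():
    return gaussian_spectrum
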