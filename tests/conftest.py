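import numpy as np
import pytest
from hypothesis import settings

from optirlipid import BandLibrary, ComponentLibrary, PowerSpectrum, Spectrum

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def bands() -> BandLibrary:
    return BandLibrary()


@pytest.fixture(scope="session")
def library() -> ComponentLibrary:
    return ComponentLibrary()


@pytest.fixture()
def flat_power() -> PowerSpectrum:
    axis = np.arange(980.0, 2302.0, 2.0)
    return PowerSpectrum(axis, np.full(axis.size, 2.0))


def gaussian_spectrum(centers, fwhms, amps, axis=None, baseline=0.0, **flags) -> Spectrum:
    """Sum-of-Gaussians test spectrum on the default scan axis."""
    if axis is None:
        axis = np.arange(980.0, 2300.0 + 1e-9, 2.0)
    axis = np.asarray(axis, dtype=float)
    y = np.full(axis.size, float(baseline))
    for c, f, a in zip(centers, fwhms, amps):
        y = y + a * np.exp(-4.0 * np.log(2.0) * ((axis - c) / f) ** 2)
    flags.setdefault("power_normalized", True)
    return Spectrum(axis, y, **flags)


@pytest.fixture(scope="session")
def make_gaussian_spectrum():
    return gaussian_spectrum
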