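import numpy as np
import pytest

from photospec.lineshapes import BandModel
from photospec.spectra import Spectrum


@pytest.fixture
def nm_grid():
    """1-nm emission grid, 600-800 nm."""
    return np.arange(600.0, 800.0 + 0.5, 1.0)


@pytest.fixture
def gaussian_spectrum(nm_grid):
    """Factory: Gaussian emission band on the standard grid."""

    def make(center=685.0, fwhm=22.0, amplitude=1.0, kind="emission", **kw):
        band = BandModel(center, fwhm, amplitude)
        return Spectrum(nm_grid, band(nm_grid), kind=kind, **kw)

    return make
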