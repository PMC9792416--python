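"""Gaussian emission lineshapes shared by the kinetic model and the
synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandModel"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandModel:
    """A Gaussian emission band in wavelength.

    The model carries a centre (nm), full width at half maximum (nm) and a
    peak amplitude. Gaussians are a generic stand-in lineshape: none of the
    downstream contracts depend on the true (vibronically structured) shape
    of chlorophyll emission.
    """

    center_nm: float
    fwhm_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm * _FWHM_TO_SIGMA

    def __call__(self, wavelengths_nm) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        z = (lam - self.center_nm) / self.sigma_nm
        return self.amplitude * np.exp(-0.5 * z * z)

    def area(self) -> float:
        """Analytic area under the band over the full line."""
        return self.amplitude * self.sigma_nm * np.sqrt(2.0 * np.pi)
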