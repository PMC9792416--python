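"""Non-negative spectral unmixing of pigment-extract absorption spectra.

An 80%-acetone extract absorption spectrum is modelled as a non-negative
linear combination of individual pigment spectra (chlorophyll a,
chlorophyll b, carotenoids). The fitted weights give pigment concentrations
via per-pigment extinction scales, and their ratio the Chl a/b ratio — the
standard diagnostic of antenna composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .spectra import Spectrum, resample

__all__ = ["PigmentBasis", "PigmentUnmixer", "unmix", "UnmixResult"]


@dataclass(frozen=True)
class PigmentBasis:
    """Named pigment spectra on a shared grid with extinction scales.

    ``extinction_scale`` converts a fitted weight into a concentration
    (weight * scale); for a basis of unit-concentration spectra the scales
    are 1.
    """

    names: tuple[str, ...]
    spectra: tuple[Spectrum, ...]
    extinction_scale: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.spectra)
                == len(self.extinction_scale)):
            raise ValueError("names/spectra/scales must align")
        grid = self.spectra[0].wavelengths_nm
        for s in self.spectra[1:]:
            if (s.wavelengths_nm.size != grid.size
                    or not np.allclose(s.wavelengths_nm, grid)):
                raise ValueError("basis spectra must share one grid")
        for s in self.spectra:
            if np.any(s.intensities < 0):
                raise ValueError("basis spectra must be non-negative")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    def matrix(self, mask=None) -> np.ndarray:
        cols = [s.intensities if mask is None else s.intensities[mask]
                for s in self.spectra]
        return np.column_stack(cols)


@dataclass(frozen=True)
class UnmixResult:
    names: tuple[str, ...]
    weights: np.ndarray
    concentrations: np.ndarray
    chl_ab_ratio: float | None
    residual_rms: float


class PigmentUnmixer(BaseEstimator):
    """Non-negative least-squares fit of an extract spectrum to a pigment
    basis (scikit-learn estimator protocol).

    Solves ``min ||extract - B w||^2, w >= 0`` over the fit window with an
    active-set NNLS solver; non-negativity is the physical constraint that
    concentrations cannot be negative.

    Attributes
    ----------
    weights_ : ndarray of fitted non-negative weights.
    concentrations_ : weights * extinction scales.
    chl_ab_ratio_ : chlorophyll a/b concentration ratio (None if the basis
        lacks either pigment).
    residual_rms_ : RMS of the fit residual over the window.
    """

    def __init__(self, basis: PigmentBasis,
                 fit_window_nm: tuple[float, float] = (350.0, 750.0)):
        self.basis = basis
        self.fit_window_nm = fit_window_nm

    def fit(self, extract: Spectrum, y=None) -> "PigmentUnmixer":
        basis = self.basis
        grid = basis.wavelengths_nm
        mask = (grid >= self.fit_window_nm[0]) & (grid <= self.fit_window_nm[1])
        if not mask.any():
            raise ValueError("fit window does not overlap the basis grid")
        B = basis.matrix(mask)
        if (extract.wavelengths_nm.size == grid.size
                and np.allclose(extract.wavelengths_nm, grid)):
            y_vec = extract.intensities[mask]
        else:
            # resample the extract onto the basis grid inside the window only
            target = grid[mask]
            y_vec = resample(extract, target).intensities
        if np.allclose(y_vec, 0):
            raise ValueError("all-zero extract spectrum")
        cond = np.linalg.cond(B)
        if cond > 1e8:
            raise ValueError(f"collinear basis (condition number {cond:.3g})")
        w, rnorm = nnls(B, y_vec)
        self.weights_ = w
        self.concentrations_ = w * np.asarray(basis.extinction_scale)
        self.residual_rms_ = float(rnorm / np.sqrt(y_vec.size))
        self.chl_ab_ratio_ = self._ab_ratio()
        self._check_kkt(B, y_vec, w)
        return self

    def _ab_ratio(self) -> float | None:
        names = self.basis.names
        if "chl_a" not in names or "chl_b" not in names:
            return None
        conc = dict(zip(names, self.concentrations_))
        if conc["chl_b"] == 0:
            return float("inf") if conc["chl_a"] > 0 else None
        return float(conc["chl_a"] / conc["chl_b"])

    def _check_kkt(self, B, y_vec, w, tol: float = 1e-6) -> None:
        """KKT conditions of the NNLS solution: gradient zero on the active
        set, non-negative on the zero set (relative to the problem scale)."""
        grad = B.T @ (B @ w - y_vec)
        scale = max(np.linalg.norm(B.T @ y_vec), 1e-300)
        active = w > 0
        if np.any(np.abs(grad[active]) > tol * scale):
            raise RuntimeError("NNLS optimality violated on active set")
        if np.any(grad[~active] < -tol * scale):
            raise RuntimeError("NNLS optimality violated on zero set")

    def result(self) -> UnmixResult:
        return UnmixResult(self.basis.names, self.weights_,
                           self.concentrations_, self.chl_ab_ratio_,
                           self.residual_rms_)


def unmix(extract: Spectrum, basis: PigmentBasis,
          fit_window_nm: tuple[float, float] = (350.0, 750.0)) -> UnmixResult:
    """Functional wrapper: fit and return the :class:`UnmixResult`."""
    return PigmentUnmixer(basis, fit_window_nm).fit(extract).result()
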