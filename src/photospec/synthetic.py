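"""Synthetic fixtures with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without measured data:

* PSI emission — bulk 685-nm band plus a red-form band whose relative
  amplitude follows the Boltzmann-equilibrium populations of the kinetic
  model at the requested temperature (so the generated series has the
  monotone red-form temperature dependence the analysis quantifies);
* PSII emission — fixed 685/695-nm doublet with a weak vibronic tail,
  temperature independent in shape;
* streak images — sums of exponential components convolved with a Gaussian
  IRF, with optional Poisson counting noise;
* acetone-extract absorption — non-negative combinations of pigment basis
  spectra plus Gaussian noise.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .das import StreakImage, emg_kernel
from .kinetics import KineticModel, steady_state
from .lineshapes import BandModel
from .spectra import Spectrum
from .unmix import PigmentBasis

__all__ = [
    "BandModel",
    "SimulationRecipe",
    "make_psi_emission",
    "make_psii_emission",
    "make_streak",
    "make_extract_absorption",
    "synthetic_pigment_basis",
]


@dataclass(frozen=True)
class SimulationRecipe:
    """Bands plus noise description for a generated spectrum."""

    bands: tuple[BandModel, ...]
    noise_model: str = "none"           # none | gaussian | poisson
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _apply_noise(values: np.ndarray, recipe: SimulationRecipe) -> np.ndarray:
    if recipe.noise_model == "none" or recipe.noise_scale == 0:
        return values
    rng = np.random.default_rng(recipe.seed)
    if recipe.noise_model == "gaussian":
        return values + rng.normal(0.0, recipe.noise_scale, values.shape)
    # poisson: noise_scale = expected counts at the spectrum maximum
    scale = recipe.noise_scale / max(values.max(), 1e-300)
    return rng.poisson(np.clip(values * scale, 0, None)) / scale


_DEFAULT_GRID = np.arange(600.0, 800.0 + 0.5, 1.0)


def make_psi_emission(temperature_K: float = 293.0,
                      red_center_nm: float = 733.0,
                      bulk_band: BandModel | None = None,
                      red_fwhm_nm: float = 32.0,
                      model: KineticModel | None = None,
                      noise_model: str = "none",
                      noise_scale: float = 0.0,
                      seed: int = 0,
                      wavelengths_nm: np.ndarray | None = None) -> Spectrum:
    """Synthetic PSI emission spectrum at a given temperature.

    The bulk (685 nm) and red (``red_center_nm``) band amplitudes are the
    steady-state pool populations of the kinetic model at ``temperature_K``,
    so cooling shifts weight into the red band: at 77 K the red band
    dominates outright, and over 280-298 K the far-red area falls with
    temperature, as in measured PSI series.
    """
    if not (250.0 <= temperature_K <= 320.0 or temperature_K == 77.0):
        raise ValueError("temperature must be 77 K or within 250-320 K")
    grid = _DEFAULT_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm)
    bulk = bulk_band or BandModel(685.0, 22.0)
    red = BandModel(red_center_nm, red_fwhm_nm)
    kin = model or KineticModel.default()
    kin = replace(kin, lineshape_bulk=bulk, lineshape_red=red)
    p_bulk, p_red = steady_state(kin, temperature_K).populations
    values = p_bulk * bulk(grid) + p_red * red(grid)
    values = values / values.max()
    recipe = SimulationRecipe((bulk, red), noise_model, noise_scale, seed)
    values = _apply_noise(values, recipe)
    return Spectrum(grid, values, kind="emission", temperature_K=temperature_K,
                    label="synthetic-PSI",
                    meta={"red_center_nm": red_center_nm, "seed": seed})


def make_psii_emission(noise_model: str = "none", noise_scale: float = 0.0,
                       seed: int = 0,
                       wavelengths_nm: np.ndarray | None = None) -> Spectrum:
    """Synthetic PSII emission: 685/695-nm bands plus a weak vibronic tail.

    The shape carries no temperature dependence — the experimental
    observation the contribution calculation relies on — so the same
    spectrum serves every temperature.
    """
    grid = _DEFAULT_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm)
    bands = (BandModel(685.0, 14.0, 1.0),
             BandModel(695.0, 16.0, 0.55),
             BandModel(742.0, 55.0, 0.16))
    values = np.sum([b(grid) for b in bands], axis=0)
    values = values / values.max()
    recipe = SimulationRecipe(bands, noise_model, noise_scale, seed)
    values = _apply_noise(values, recipe)
    return Spectrum(grid, values, kind="emission", temperature_K=293.0,
                    label="synthetic-PSII", meta={"seed": seed})


def make_streak(components: Sequence[tuple[float, Spectrum]],
                irf_fwhm_ps: float = 16.0,
                time_window_ps: float = 800.0,
                dt_ps: float = 2.0,
                bin_nm: float = 5.0,
                counts_scale: float = 1.0e4,
                t0_ps: float = 30.0,
                poisson_noise: bool = True,
                seed: int = 0) -> StreakImage:
    """Synthetic streak image from (lifetime, DAS spectrum) components.

    The noiseless signal is ``sum_i DAS_i(l) * (exp(-t/tau_i) (x) IRF)(t)``
    with the analytic exponentially-modified-Gaussian kernel; Poisson
    counting noise is then sampled with ``counts_scale`` expected counts at
    the signal maximum. Negative DAS amplitudes (transfer components) are
    allowed; any negative expected counts are clipped at zero with a
    warning before sampling.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    taus = [tau for tau, _ in components]
    if any(tau <= 0 for tau in taus):
        raise ValueError("lifetimes must be positive")
    spectra = [s for _, s in components]
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    wl = np.arange(lo + bin_nm / 2.0, hi, bin_nm)
    times = np.arange(0.0, time_window_ps + dt_ps / 2.0, dt_ps)
    signal = np.zeros((times.size, wl.size))
    for tau, spec in components:
        das = np.interp(wl, spec.wavelengths_nm, spec.intensities)
        signal += np.outer(emg_kernel(times, tau, irf_fwhm_ps, t0_ps), das)
    if signal.min() < 0:
        warnings.warn("negative expected counts clipped at zero",
                      RuntimeWarning, stacklevel=2)
        signal = np.clip(signal, 0.0, None)
    expected = signal * (counts_scale / max(signal.max(), 1e-300))
    if poisson_noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return StreakImage(times, wl, counts, irf_fwhm_ps=irf_fwhm_ps,
                       irf_t0_ps=t0_ps)


def synthetic_pigment_basis(wavelengths_nm: np.ndarray | None = None
                            ) -> PigmentBasis:
    """Gaussian stand-in pigment basis (synthetic, not measured extinction
    spectra): chlorophyll a and b Soret + Qy bands and a carotenoid band.

    Real pigment spectra are user-supplied files; this basis exists so the
    unmixing machinery is testable end to end.
    """
    grid = (np.arange(350.0, 750.0 + 0.5, 1.0) if wavelengths_nm is None
            else np.asarray(wavelengths_nm))

    def pig(bands):
        vals = np.sum([b(grid) for b in bands], axis=0)
        return Spectrum(grid, vals, kind="absorption", label="synthetic-pigment")

    chl_a = pig([BandModel(430.0, 30.0, 1.0), BandModel(662.0, 20.0, 0.8)])
    chl_b = pig([BandModel(455.0, 30.0, 1.0), BandModel(645.0, 22.0, 0.45)])
    car = pig([BandModel(450.0, 25.0, 0.6), BandModel(480.0, 25.0, 0.55)])
    return PigmentBasis(names=("chl_a", "chl_b", "carotenoid"),
                        spectra=(chl_a, chl_b, car),
                        extinction_scale=(1.0, 1.0, 1.0))


def make_extract_absorption(concentrations, basis: PigmentBasis,
                            noise_scale: float = 0.0,
                            seed: int = 0) -> Spectrum:
    """Acetone-extract absorption: weighted sum of pigment basis spectra
    plus Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size != len(basis.names):
        raise ValueError("one concentration per basis pigment required")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    grid = basis.spectra[0].wavelengths_nm
    values = np.zeros_like(grid)
    for w, spec in zip(conc, basis.spectra):
        values = values + w * spec.intensities
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_scale, values.shape)
    return Spectrum(grid, values, kind="absorption", label="synthetic-extract",
                    meta={"seed": seed})
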