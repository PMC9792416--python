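"""PSI share of detector-filtered leaf fluorescence in F0 and FM.

Pulse-amplitude-modulation (PAM) fluorometry reads the PSII quantum
efficiency off the ratio Fv/FM = 1 - F0/FM of minimal (open reaction
centres) to maximal (closed centres) fluorescence, detected through a
far-red long-pass filter (RG9 in most instruments). PSI also emits in that
detection band, at a yield that does not respond to PSII closure, so it
contaminates both levels.

The estimate: normalise the PSI and PSII emission spectra to unit total
area, weight each by the filter transmission and integrate to get the
transmitted signal per photosystem, then scale by fluorescence lifetimes
(proportional to quantum yield): 69 ps for PSI, 224 ps for open PSII and
1.6 ns for closed PSII. Equal excitation of the photosystems is assumed
unless an excitation ratio is given.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .spectra import (FilterCurve, Spectrum, common_grid, integrate,
                      read_filter_curve, resample)

__all__ = [
    "ContributionResult",
    "psi_contribution",
    "contribution_vs_temperature",
    "unit_filter",
    "rg9_filter",
]


@dataclass(frozen=True)
class ContributionResult:
    """PSI fraction of filtered fluorescence in F0 and FM, and Fv/FM."""

    f0_psi_fraction: float
    fm_psi_fraction: float
    fv_over_fm: float
    tau_psi_ps: float
    tau_psii_open_ps: float
    tau_psii_closed_ps: float
    filter_name: str = ""
    temperature_K: float | None = None

    def __post_init__(self) -> None:
        for name in ("f0_psi_fraction", "fm_psi_fraction", "fv_over_fm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _transmitted_signal(spectrum: Spectrum, filt: FilterCurve,
                        restrict_above_nm: float | None) -> float:
    """Unit-area-normalised spectrum weighted by the filter and integrated."""
    total = integrate(spectrum)
    if total <= 0:
        raise ValueError("spectrum has non-positive total area")
    wl = spectrum.wavelengths_nm
    weighted = spectrum.intensities / total * filt(wl)
    s = Spectrum(wl, weighted, kind=spectrum.kind,
                 temperature_K=spectrum.temperature_K)
    if restrict_above_nm is None:
        return integrate(s)
    if wl[-1] <= restrict_above_nm:
        raise ValueError("spectrum does not extend beyond the restriction")
    return integrate(s, (max(restrict_above_nm, wl[0]), wl[-1]))


def psi_contribution(psi: Spectrum, psii: Spectrum, filter: FilterCurve,
                     tau_psi_ps: float = 69.0,
                     tau_psii_open_ps: float = 224.0,
                     tau_psii_closed_ps: float = 1600.0,
                     excitation_ratio: float = 1.0,
                     restrict_above_nm: float | None = None
                     ) -> ContributionResult:
    """PSI contribution to filtered fluorescence in the F0 and FM states.

    With transmitted signals ``s_i`` (unit-area spectra times filter,
    integrated) and excitation ratio ``r`` (PSI relative to PSII):

        F0 = s_PSI * tau_PSI * r + s_PSII * tau_open
        FM = s_PSI * tau_PSI * r + s_PSII * tau_closed
        Fv/FM = 1 - F0/FM

    ``restrict_above_nm`` optionally limits the transmitted-signal integral
    to wavelengths above a cutoff; with a genuine long-pass filter the
    difference is negligible.
    """
    grid = common_grid([psi, psii])
    psi_r = resample(psi, grid)
    psii_r = resample(psii, grid)
    s_psi = _transmitted_signal(psi_r, filter, restrict_above_nm)
    s_psii = _transmitted_signal(psii_r, filter, restrict_above_nm)
    if s_psi <= 0 or s_psii <= 0:
        raise ValueError("filter blocks one of the spectra entirely")
    psi_term = s_psi * tau_psi_ps * excitation_ratio
    f0_total = psi_term + s_psii * tau_psii_open_ps
    fm_total = psi_term + s_psii * tau_psii_closed_ps
    return ContributionResult(
        f0_psi_fraction=psi_term / f0_total,
        fm_psi_fraction=psi_term / fm_total,
        fv_over_fm=1.0 - f0_total / fm_total,
        tau_psi_ps=tau_psi_ps,
        tau_psii_open_ps=tau_psii_open_ps,
        tau_psii_closed_ps=tau_psii_closed_ps,
        filter_name=filter.name,
        temperature_K=psi.temperature_K,
    )


def contribution_vs_temperature(psi_series, psii: Spectrum,
                                filter: FilterCurve,
                                **lifetimes) -> list[ContributionResult]:
    """Apply :func:`psi_contribution` across a PSI temperature series with
    one fixed PSII spectrum (PSII emission shape is temperature
    independent); returns results sorted by temperature."""
    series = sorted(psi_series, key=lambda s: s.temperature_K)
    if not series:
        raise ValueError("empty PSI series")
    return [psi_contribution(psi, psii, filter, **lifetimes) for psi in series]


def unit_filter(lo_nm: float = 300.0, hi_nm: float = 900.0) -> FilterCurve:
    """Fully transmitting filter over [lo, hi] nm (for closed-form checks)."""
    return FilterCurve(np.array([lo_nm, hi_nm]), np.array([1.0, 1.0]),
                       name="unit")


def rg9_filter() -> FilterCurve:
    """Packaged far-red long-pass transmission curve.

    This is a synthetic stand-in emulating an RG9-class coloured-glass
    long-pass (cut-on near 705 nm, ~88% plateau transmission); instruments
    should be modelled with the manufacturer's tabulated curve supplied as a
    user file.
    """
    ref = importlib.resources.files("photospec.data") / "rg9_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_filter_curve(path, name="RG9(synthetic)")
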