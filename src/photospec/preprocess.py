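"""Spectrum preprocessing: scattering correction, normalisation, smoothing,
peak location and the red-form temperature statistic.

The steady-state pipeline mirrors standard practice for chlorophyll-protein
spectroscopy: absorption spectra are zeroed at 750 nm and descattered with a
linear baseline whose slope is the mean slope over 750-800 nm, then
area-normalised over 650-750 nm; emission spectra are Savitzky-Golay
smoothed and peak-normalised. The red-form statistic tracks, as a function
of sample temperature, the far-red (700-800 nm) emission of photosystem I
relative to its bulk 685-nm peak, referenced to the 293 K measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectralPeak, integrate

__all__ = [
    "RedFormSeries",
    "zero_and_descatter",
    "normalize_area",
    "savgol",
    "normalize_peak",
    "find_lambda_max",
    "red_form_statistic",
    "recovery_check",
]


@dataclass(frozen=True)
class RedFormSeries:
    """Relative far-red emission area versus temperature.

    ``relative_area`` is 1 at the reference temperature (293 K by default);
    ``se`` holds optional standard errors over technical replicates.
    """

    temperatures_K: tuple[float, ...]
    relative_area: tuple[float, ...]
    reference_K: float = 293.0
    se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures_K) != len(self.relative_area):
            raise ValueError("temperatures and areas must have equal length")
        if self.se is not None and len(self.se) != len(self.relative_area):
            raise ValueError("se length mismatch")


def _slope_window_mean(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Mean finite-difference slope of the spectrum over a window."""
    wl, inten = spectrum.wavelengths_nm, spectrum.intensities
    mask = (wl >= window[0]) & (wl <= window[1])
    if mask.sum() < 2:
        raise ValueError(f"grid does not cover slope window {window}")
    x, y = wl[mask], inten[mask]
    return float(np.mean(np.diff(y) / np.diff(x)))


def zero_and_descatter(spectrum: Spectrum, zero_at_nm: float = 750.0,
                       slope_window_nm: tuple[float, float] = (750.0, 800.0),
                       ) -> Spectrum:
    """Zero an absorption spectrum at ``zero_at_nm`` and remove the linear
    scattering baseline.

    The subtracted line is ``m * (lambda - zero_at) + A(zero_at)`` with ``m``
    the mean finite-difference slope over ``slope_window_nm``, so the output
    is exactly zero at ``zero_at_nm`` and has zero mean slope over the window.
    A spectrum that is already flat and zero beyond the red edge is returned
    unchanged (up to floating point).
    """
    if spectrum.kind != "absorption":
        raise ValueError("scattering correction applies to absorption spectra")
    wl = spectrum.wavelengths_nm
    if wl[0] > zero_at_nm or wl[-1] < slope_window_nm[1]:
        raise ValueError(
            f"grid [{wl[0]}, {wl[-1]}] must cover {zero_at_nm} nm and "
            f"the slope window {slope_window_nm}"
        )
    m = _slope_window_mean(spectrum, slope_window_nm)
    offset = spectrum.value_at(zero_at_nm)
    baseline = m * (wl - zero_at_nm) + offset
    return spectrum.with_intensities(
        spectrum.intensities - baseline,
        descatter=f"zero@{zero_at_nm:g},slope{slope_window_nm}",
    )


def normalize_area(spectrum: Spectrum,
                   window_nm: tuple[float, float] = (650.0, 750.0)) -> Spectrum:
    """Scale the spectrum so its trapezoidal area over ``window_nm`` is 1."""
    area = integrate(spectrum, window_nm)
    if area <= 0:
        raise ValueError(f"non-positive area {area:g} in window {window_nm}")
    return spectrum.with_intensities(spectrum.intensities / area,
                                     normalized=f"area{window_nm}")


def savgol(spectrum: Spectrum, window_points: int = 21, order: int = 2) -> Spectrum:
    """Savitzky-Golay smooth on a uniform wavelength grid.

    ``window_points`` must be odd and larger than ``order``. Edges are
    handled by evaluating the polynomial fitted to the last full window
    (scipy's ``mode='interp'``), so an input that is globally a polynomial
    of degree <= ``order`` is reproduced exactly.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= order:
        raise ValueError("window_points must exceed the polynomial order")
    steps = np.diff(spectrum.wavelengths_nm)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("grid is not uniform; resample onto a uniform grid first")
    if window_points > len(spectrum):
        raise ValueError("window longer than the spectrum")
    smoothed = savgol_filter(spectrum.intensities, window_points, order,
                             mode="interp")
    return spectrum.with_intensities(smoothed,
                                     smoothed=f"savgol({window_points},{order})")


def normalize_peak(spectrum: Spectrum,
                   window_nm: tuple[float, float]) -> Spectrum:
    """Scale the spectrum so the maximum intensity inside ``window_nm`` is 1."""
    wl = spectrum.wavelengths_nm
    mask = (wl >= window_nm[0]) & (wl <= window_nm[1])
    if not mask.any():
        raise ValueError(f"window {window_nm} does not overlap the grid")
    peak = spectrum.intensities[mask].max()
    if peak <= 0:
        raise ValueError(f"no positive intensity in window {window_nm}")
    return spectrum.with_intensities(spectrum.intensities / peak,
                                     normalized=f"peak{window_nm}")


def find_lambda_max(spectrum: Spectrum,
                    window_nm: tuple[float, float]) -> SpectralPeak:
    """Locate the emission maximum inside a window with sub-grid precision.

    A parabola through the grid argmax and its two neighbours provides the
    vertex; measured emission maxima are routinely quoted with sub-nanometre
    precision on 1-nm grids, which grid argmax alone cannot support. At a
    window edge the raw argmax is returned with ``flag="edge"``; a plateau
    of more than three equal maxima returns the plateau centre with
    ``flag="plateau"``.
    """
    wl, inten = spectrum.wavelengths_nm, spectrum.intensities
    mask = (wl >= window_nm[0]) & (wl <= window_nm[1])
    if not mask.any():
        raise ValueError(f"window {window_nm} does not overlap the grid")
    idx = np.flatnonzero(mask)
    sub = inten[idx]
    peak_val = sub.max()
    ties = idx[sub == peak_val]
    if ties.size > 3:
        centre = float(np.mean(wl[ties]))
        return SpectralPeak(centre, float(peak_val), tuple(window_nm),
                            flag="plateau")
    i = int(ties[0])
    if i == idx[0] or i == idx[-1] or i == 0 or i == len(wl) - 1:
        return SpectralPeak(float(wl[i]), float(inten[i]), tuple(window_nm),
                            flag="edge")
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature: keep grid argmax
        return SpectralPeak(float(x1), float(y1), tuple(window_nm), flag="edge")
    vertex = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    height = a * vertex**2 + b * vertex + c
    vertex = float(np.clip(vertex, window_nm[0], window_nm[1]))
    return SpectralPeak(vertex, float(height), tuple(window_nm))


def red_form_statistic(series: Sequence[Spectrum], reference_K: float = 293.0,
                       red_window_nm: tuple[float, float] = (700.0, 800.0),
                       peak_window_nm: tuple[float, float] = (675.0, 690.0),
                       zero_min_first: bool = True) -> RedFormSeries:
    """Relative far-red emission area of a temperature series.

    Per spectrum: subtract the minimum (before or after the implicit peak
    normalisation, controlled by ``zero_min_first``), normalise to the bulk
    peak inside ``peak_window_nm`` (this absorbs photodamage between
    temperature steps), integrate the red window, then divide every value by
    the value at ``reference_K``. If the reference temperature was not
    measured its value is obtained by linear interpolation between the
    neighbouring temperatures.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 temperatures")
    temps = np.array([s.temperature_K for s in series], dtype=float)
    order = np.argsort(temps)
    temps = temps[order]
    areas = []
    for k in order:
        s = series[k]
        if zero_min_first:
            s = s.with_intensities(s.intensities - s.intensities.min())
            s = normalize_peak(s, peak_window_nm)
        else:
            s = normalize_peak(s, peak_window_nm)
            s = s.with_intensities(s.intensities - s.intensities.min())
        areas.append(integrate(s, red_window_nm))
    areas = np.asarray(areas)
    if not (temps[0] <= reference_K <= temps[-1]):
        raise ValueError(
            f"reference {reference_K} K not bracketed by measured "
            f"temperatures [{temps[0]}, {temps[-1]}] K"
        )
    ref_area = float(np.interp(reference_K, temps, areas))
    if ref_area <= 0:
        raise ValueError("reference red-window area is not positive")
    return RedFormSeries(tuple(temps), tuple(areas / ref_area),
                         reference_K=reference_K)


def recovery_check(before: Spectrum, after: Spectrum,
                   red_window_nm: tuple[float, float] = (700.0, 800.0)) -> float:
    """Ratio of far-red area after/before a heating cycle (1 = full recovery).

    Both spectra must be recorded at the same nominal temperature; the check
    quantifies irreversible photodamage accrued during a temperature sweep.
    """
    if abs(before.temperature_K - after.temperature_K) > 1.0:
        raise ValueError(
            f"recovery check needs matching temperatures, got "
            f"{before.temperature_K} K and {after.temperature_K} K"
        )
    ref = integrate(before, red_window_nm)
    if ref <= 0:
        raise ValueError("zero red-window area in the reference spectrum")
    return integrate(after, red_window_nm) / ref
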