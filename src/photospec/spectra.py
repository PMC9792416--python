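"""Core spectral containers and grid arithmetic.

Everything downstream (preprocessing, global lifetime analysis, the
temperature model, the PAM-contribution calculation) works on the two
containers defined here: :class:`Spectrum`, a wavelength/intensity table
with acquisition metadata, and :class:`FilterCurve`, a tabulated
transmission curve evaluated by linear interpolation.

Wavelengths are nanometres throughout; intensities are instrument units
(fluorescence counts or optical density) and carry no unit object.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "FilterCurve",
    "SpectralPeak",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_filter_curve",
    "integrate",
    "resample",
]

_KIND_VALUES = ("absorption", "emission")


class SpectrumParseError(ValueError):
    """Raised when a spectral table cannot be parsed."""


@dataclass(frozen=True)
class Spectrum:
    """A single measured or modelled spectrum on a strictly ascending grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid, nm.
    intensities
        Intensity at each grid point (counts or OD; arbitrary units).
    kind
        ``"absorption"`` or ``"emission"``.
    temperature_K
        Sample temperature in kelvin (77 for cryogenic measurements).
    label
        Free-text species/replicate/condition tag.
    meta
        Additional key-value metadata carried through transformations.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    kind: str = "emission"
    temperature_K: float = 293.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.size != inten.size:
            raise ValueError(
                f"grid length {wl.size} != intensity length {inten.size}"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in _KIND_VALUES:
            raise ValueError(f"kind must be one of {_KIND_VALUES}, got {self.kind!r}")
        if not self.temperature_K > 0:
            raise ValueError("temperature_K must be positive")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new intensities, metadata preserved."""
        new_meta = {**self.meta, **meta_updates}
        return replace(self, intensities=np.asarray(intensities, float), meta=new_meta)

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated intensity at ``wavelength_nm`` (in range)."""
        wl = float(wavelength_nm)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not (lo <= wl <= hi):
            raise ValueError(f"{wl} nm outside recorded range [{lo}, {hi}] nm")
        return float(np.interp(wl, self.wavelengths_nm, self.intensities))


@dataclass(frozen=True)
class FilterCurve:
    """Tabulated transmission of an optical filter.

    Between tabulated points transmission is linear; outside the tabulated
    range the filter is treated as fully blocking (transmission 0), which is
    the physical behaviour of a coloured-glass long-pass on its short side.
    """

    wavelengths_nm: np.ndarray
    transmission: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        tr = np.asarray(self.transmission, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "transmission", tr)
        if wl.size != tr.size or wl.size < 2:
            raise ValueError("filter curve needs matching grids of length >= 2")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("filter wavelength grid must be strictly increasing")
        if np.any(tr < 0) or np.any(tr > 1):
            raise ValueError("transmission must lie in [0, 1]")

    def __call__(self, wavelengths_nm) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        return np.interp(lam, self.wavelengths_nm, self.transmission,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class SpectralPeak:
    """Location of an emission/absorption maximum inside a search window.

    ``flag`` is ``None`` for a clean interior peak, ``"edge"`` when the
    maximum sits on the window boundary (no parabolic refinement possible)
    and ``"plateau"`` when more than three grid points tie at the maximum.
    """

    lambda_max_nm: float
    intensity_at_max: float
    search_window_nm: tuple[float, float]
    flag: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.search_window_nm
        if not (lo <= self.lambda_max_nm <= hi):
            raise ValueError("lambda_max must lie inside the search window")


# ---------------------------------------------------------------------------
# I/O: two-column delimited text with '#' key=value headers
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"^\s*#\s*([A-Za-z_][\w.]*)\s*=\s*(.+?)\s*$")


def _parse_two_column(text: str, source: str) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        # delimiter sniffing: comma, tab or whitespace
        parts = [p for p in re.split(r"[,\t;]+|\s+", line) if p]
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{source}, line {lineno}: expected 2 columns, got {len(parts)}"
            )
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{source}, line {lineno}: non-numeric field in {line!r}"
            ) from exc
    if len(xs) < 2:
        raise SpectrumParseError(f"{source}: fewer than 2 data points")
    x = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        dup = x[np.flatnonzero(np.diff(x) == 0)[0]]
        raise SpectrumParseError(f"{source}: duplicate wavelength {dup:g} nm")
    return x, y, meta


def read_spectrum(path, kind: str | None = None,
                  metadata: Mapping | None = None) -> Spectrum:
    """Read a two-column (wavelength, intensity) table into a :class:`Spectrum`.

    ``#``-prefixed ``key=value`` header lines populate the metadata; explicit
    ``kind``/``metadata`` arguments override the header. Rows are sorted by
    wavelength; duplicate wavelengths are rejected.
    """
    path = Path(path)
    x, y, meta = _parse_two_column(path.read_text(), str(path))
    if metadata:
        meta.update(metadata)
    kind = kind or meta.pop("kind", "emission")
    temperature = float(meta.pop("temperature_K", 293.0))
    label = str(meta.pop("label", meta.pop("species", "")))
    return Spectrum(x, y, kind=kind, temperature_K=temperature,
                    label=label, meta=meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as tab-separated text with ``# key=value`` headers.

    Values round-trip through :func:`read_spectrum` at full float precision.
    """
    buf = io.StringIO()
    buf.write(f"# kind={spectrum.kind}\n")
    buf.write(f"# temperature_K={float(spectrum.temperature_K)!r}\n")
    if spectrum.label:
        buf.write(f"# label={spectrum.label}\n")
    for key, value in spectrum.meta.items():
        buf.write(f"# {key}={value}\n")
    for wl, inten in zip(spectrum.wavelengths_nm, spectrum.intensities):
        buf.write(f"{float(wl)!r}\t{float(inten)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_filter_curve(path, name: str = "") -> FilterCurve:
    """Read a filter transmission table.

    Accepts transmission either as a fraction in [0, 1] or in percent;
    percent input is detected by a maximum above 1.5 and rescaled.
    """
    path = Path(path)
    x, y, meta = _parse_two_column(path.read_text(), str(path))
    if y.max() > 1.5:  # percent
        y = y / 100.0
    y = np.clip(y, 0.0, 1.0)
    return FilterCurve(x, y, name=name or meta.get("name", path.stem))


# ---------------------------------------------------------------------------
# Grid arithmetic
# ---------------------------------------------------------------------------

def integrate(spectrum: Spectrum, window_nm: tuple[float, float] | None = None) -> float:
    """Trapezoidal area of the spectrum over a closed wavelength window.

    Window endpoints falling between grid points are included by linear
    interpolation, so the result is exact for piecewise-linear spectra and
    additive over adjacent windows. With ``window_nm=None`` the full recorded
    range is integrated.
    """
    wl, inten = spectrum.wavelengths_nm, spectrum.intensities
    if window_nm is None:
        return float(np.trapezoid(inten, wl))
    lo, hi = float(window_nm[0]), float(window_nm[1])
    if hi < lo:
        raise ValueError("window must have lo <= hi")
    lo = max(lo, wl[0])
    hi = min(hi, wl[-1])
    if hi <= lo:
        raise ValueError(
            f"window [{window_nm[0]}, {window_nm[1]}] does not overlap the "
            f"grid [{wl[0]}, {wl[-1]}]"
        )
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, wl, inten)
    return float(np.trapezoid(vals, grid))


def resample(spectrum: Spectrum, grid_nm, fill_value: float | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto a new ascending grid.

    Extrapolation beyond the recorded range raises unless an explicit
    ``fill_value`` is supplied. Metadata is preserved.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("target grid must be 1-D, strictly increasing, length >= 2")
    wl = spectrum.wavelengths_nm
    outside = (grid < wl[0]) | (grid > wl[-1])
    if outside.any() and fill_value is None:
        bad = grid[outside][0]
        raise ValueError(
            f"resample target {bad:g} nm outside recorded range "
            f"[{wl[0]:g}, {wl[-1]:g}] nm; pass fill_value to allow"
        )
    vals = np.interp(grid, wl, spectrum.intensities,
                     left=fill_value, right=fill_value)
    return replace(spectrum, wavelengths_nm=grid, intensities=vals)


def common_grid(spectra: Iterable[Spectrum], step_nm: float = 1.0) -> np.ndarray:
    """Finest common wavelength grid covering the overlap of all spectra."""
    spectra = list(spectra)
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra do not overlap in wavelength")
    n = int(np.floor((hi - lo) / step_nm)) + 1
    return lo + step_nm * np.arange(n)
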