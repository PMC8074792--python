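"""Excitation spectra and the di-8-ANEPPS dipole-potential band ratio.

di-8-ANEPPS is an electrochromic styryl dye: raising the intramembrane dipole
potential blue-shifts its excitation spectrum. The standard readout is the
ratio of fluorescence intensity integrated over the blue edge (410-440 nm) to
the red edge (490-520 nm) of the excitation spectrum, which therefore
correlates positively with the dipole potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectrumScan",
    "BLUE_BAND_NM",
    "RED_BAND_NM",
    "background_subtract",
    "integrate_band",
    "excitation_ratio",
]

#: Excitation bands (nm) of the dipole-potential-sensitive ratio.
BLUE_BAND_NM = (410.0, 440.0)
RED_BAND_NM = (490.0, 520.0)


@dataclass
class SpectrumScan:
    """An excitation scan: intensity vs excitation wavelength at fixed emission."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    emission_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 2:
            raise ValueError("a spectrum needs at least 2 wavelength points")
        if self.intensities.shape != self.wavelengths_nm.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


def background_subtract(scan: SpectrumScan, blank: SpectrumScan) -> SpectrumScan:
    """Pointwise blank subtraction on identical wavelength grids.

    Negative results are retained; their count is flagged in ``meta``.
    """
    if not np.array_equal(scan.wavelengths_nm, blank.wavelengths_nm):
        raise ValueError("scan and blank wavelength grids differ")
    diff = scan.intensities - blank.intensities
    meta = dict(scan.meta)
    meta["background_subtracted"] = True
    meta["n_negative_after_subtraction"] = int((diff < 0).sum())
    return replace(scan, intensities=diff, meta=meta)


def integrate_band(scan: SpectrumScan, lo_nm: float, hi_nm: float) -> float:
    """Trapezoidal band integral over [lo_nm, hi_nm], both limits inclusive.

    The integrand is evaluated exactly at the band limits by linear
    interpolation when they fall between grid points, so the result is exact
    for the piecewise-linear interpolant of the sampled spectrum and the
    integral is additive over adjacent bands.
    """
    wl, it = scan.wavelengths_nm, scan.intensities
    if lo_nm >= hi_nm:
        raise ValueError(f"band limits must satisfy lo < hi, got [{lo_nm}, {hi_nm}]")
    if lo_nm < wl[0] or hi_nm > wl[-1]:
        raise ValueError(
            f"band [{lo_nm}, {hi_nm}] nm outside scan range [{wl[0]}, {wl[-1]}] nm")
    inside = (wl > lo_nm) & (wl < hi_nm)
    xs = np.concatenate(([lo_nm], wl[inside], [hi_nm]))
    ys = np.concatenate(([np.interp(lo_nm, wl, it)], it[inside], [np.interp(hi_nm, wl, it)]))
    return float(np.trapezoid(ys, xs))


def excitation_ratio(scan: SpectrumScan,
                     blue_band: tuple[float, float] = BLUE_BAND_NM,
                     red_band: tuple[float, float] = RED_BAND_NM) -> float:
    """Blue-edge / red-edge excitation band intensity ratio (dimensionless).

    Positively correlates with the magnitude of the membrane dipole potential.
    """
    numerator = integrate_band(scan, *blue_band)
    denominator = integrate_band(scan, *red_band)
    if denominator <= 0:
        raise ValueError(f"red-edge band integral is non-positive ({denominator})")
    return numerator / denominator
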