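"""Xanthommatin absorption spectra and pH-titration analysis.

Xanthommatin (Xa), the ommochrome pigment of chromatophore granules, changes
color with protonation state: pale yellow (λmax ≈ 430 nm) below pH ~3,
darkening through a transition that saturates near pH 7.7.  Two ingredients
quantify this:

- absorption spectra built from quantum-chemistry excited-state line lists
  (wavelength + oscillator strength, typically the first 200 states) by
  Lorentzian broadening with a 30 nm full width at half maximum, applied in
  the wavelength domain (an energy-domain variant is provided, since
  electronic-structure broadening is often done in eV);
- a two-state Henderson–Hasselbalch model for the absorbance at 430 nm as a
  function of pH, fitted by least squares to extract the transition midpoint
  pK and the acid/base plateau absorbances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_FWHM_NM = 30.0
DEFAULT_ABS_GRID_NM = np.arange(300.0, 701.0, 1.0)
TITRATION_WAVELENGTH_NM = 430.0
_EV_NM = 1239.84193  # hc in eV·nm


@dataclass(frozen=True)
class ExcitedStateTable:
    """Excited-state line list: wavelengths (nm) and oscillator strengths."""

    wavelengths_nm: tuple[float, ...]
    strengths: tuple[float, ...]
    label: str = ""  # protonation-state label, e.g. "neutral" or "+3"

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != len(self.strengths):
            raise ValueError("wavelengths and strengths differ in length")
        if any(w <= 0 for w in self.wavelengths_nm):
            raise ValueError("excitation wavelengths must be positive")
        if any(f < 0 for f in self.strengths):
            raise ValueError("oscillator strengths must be >= 0")
        if len(self.wavelengths_nm) > 200:
            warnings.warn(
                f"{len(self.wavelengths_nm)} excited states; typical line "
                "lists carry at most the first 200",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Broadened absorption intensity (arbitrary units) on a nm grid."""

    wavelengths_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if (inten < 0).any():
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensity", inten)

    def at(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.intensity))

    def normalized(self) -> "AbsorptionSpectrum":
        peak = self.intensity.max()
        if peak == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return AbsorptionSpectrum(self.wavelengths_nm, self.intensity / peak)


def lorentzian_broaden(
    states: ExcitedStateTable,
    fwhm_nm: float = DEFAULT_FWHM_NM,
    grid_nm: np.ndarray | Sequence[float] = DEFAULT_ABS_GRID_NM,
    domain: str = "wavelength",
) -> AbsorptionSpectrum:
    """Broaden a line list into a spectrum with Lorentzian profiles.

    Each line contributes ``f_i · (γ/2)² / ((λ − λ_i)² + (γ/2)²)`` with
    γ = FWHM, so an isolated line peaks at exactly ``f_i`` at its center and
    at half that value ± FWHM/2 away.  ``domain="energy"`` broadens in eV
    instead (FWHM interpreted in eV on the energy axis).
    """
    if not states.wavelengths_nm:
        raise ValueError("excited-state table is empty")
    if fwhm_nm <= 0:
        raise ValueError("FWHM must be positive")
    grid = np.asarray(grid_nm, dtype=float)
    half = fwhm_nm / 2.0
    intensity = np.zeros_like(grid)
    for lam, f in zip(states.wavelengths_nm, states.strengths):
        if domain == "wavelength":
            intensity += f * half**2 / ((grid - lam) ** 2 + half**2)
        elif domain == "energy":
            e_grid, e_line = _EV_NM / grid, _EV_NM / lam
            intensity += f * half**2 / ((e_grid - e_line) ** 2 + half**2)
        else:
            raise ValueError(f"unknown broadening domain {domain!r}")
    return AbsorptionSpectrum(wavelengths_nm=grid, intensity=intensity)


def lambda_max_abs(spectrum: AbsorptionSpectrum) -> float:
    """Wavelength of maximum intensity (nm); ties resolve to the lowest."""
    inten = spectrum.intensity
    if not (inten > 0).any():
        raise ValueError("all-zero spectrum has no maximum")
    if np.allclose(inten, inten[0]):
        logger.warning("flat spectrum; reporting the left edge")
    return float(spectrum.wavelengths_nm[int(np.argmax(inten))])


def strongest_line(states: ExcitedStateTable) -> float:
    """Wavelength (nm) of the strongest single excitation.

    Reported alongside the broadened-envelope maximum, since a peak printed
    for a computed spectrum may refer to either.
    """
    i = int(np.argmax(states.strengths))
    return float(states.wavelengths_nm[i])


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered (pH, absorbance-at-430 nm) pairs."""

    ph: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ph.shape != ab.shape or ph.ndim != 1:
            raise ValueError("pH and absorbance must be matching 1-D arrays")
        if (ph < 0).any() or (ph > 14).any():
            raise ValueError("pH values must lie in [0, 14]")
        if (ab < 0).any():
            raise ValueError("absorbance must be non-negative")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.ph.size


@dataclass(frozen=True)
class TitrationFit:
    """Two-state titration fit: midpoint pK, plateaus, slope, residual."""

    pk: float
    a_acid: float
    a_base: float
    slope: float
    rss: float

    def __post_init__(self) -> None:
        if not 0 <= self.pk <= 14:
            raise ValueError("fitted pK outside [0, 14]")
        if self.a_acid < 0 or self.a_base < 0:
            raise ValueError("plateau absorbances must be >= 0")


def titration_model(
    pk: float,
    a_acid: float,
    a_base: float,
    slope: float,
    ph: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Two-state Henderson–Hasselbalch absorbance curve.

    ``A(pH) = A_acid + (A_base − A_acid) / (1 + 10^{slope (pK − pH)})`` —
    monotone between the acid and base plateaus, with midpoint at pH = pK.
    """
    if slope <= 0:
        raise ValueError("slope coefficient must be positive")
    ph = np.asarray(ph, dtype=float)
    return a_acid + (a_base - a_acid) / (1.0 + 10.0 ** (slope * (pk - ph)))


def fit_titration(series: TitrationSeries) -> TitrationFit:
    """Least-squares fit of the two-state model to a titration series.

    Initialization is deterministic: plateau guesses are the extreme
    absorbances, pK starts at the pH whose absorbance is closest to
    half-range, slope starts at 1.  Needs ≥ 4 points and a non-flat series.
    """
    if len(series) < 4:
        raise ValueError("titration fit needs at least 4 points")
    ab, ph = series.absorbance, series.ph
    rng_ab = float(ab.max() - ab.min())
    if rng_ab < 1e-12 or rng_ab < 1e-6 * max(ab.max(), 1.0):
        raise ValueError("degenerate fit: absorbance series is flat")

    order = np.argsort(ph)
    ph_s, ab_s = ph[order], ab[order]
    a_acid0 = float(ab_s[0])
    a_base0 = float(ab_s[-1])
    half = 0.5 * (ab.min() + ab.max())
    pk0 = float(ph[np.argmin(np.abs(ab - half))])

    def model(x, pk, a_acid, a_base, slope):
        return titration_model(pk, a_acid, a_base, slope, x)

    popt, _ = curve_fit(
        model,
        ph,
        ab,
        p0=[pk0, a_acid0, a_base0, 1.0],
        bounds=([0.0, 0.0, 0.0, 1e-3], [14.0, np.inf, np.inf, 10.0]),
        maxfev=20000,
    )
    pk, a_acid, a_base, slope = map(float, popt)
    rss = float(np.sum((model(ph, *popt) - ab) ** 2))
    return TitrationFit(pk=pk, a_acid=a_acid, a_base=a_base, slope=slope, rss=rss)
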