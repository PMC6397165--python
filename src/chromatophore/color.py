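"""Spectrum → sRGB rendering via CIE 1931 2° color matching functions.

The color matching functions use the analytic multi-lobe Gaussian fit of
the CIE 1931 2° standard observer (piecewise-Gaussian lobes), which is
accurate to a few percent across the visible band — ample for rendering the
perceived color of a reflectance spectrum as a swatch.

Rendering is relative to the perfect diffuser: linear RGB of the stimulus is
divided channel-wise by linear RGB of the illuminant, so a flat unit
reflectance maps to white regardless of illuminant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def _lobe(wl: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    t = (wl - mu) * np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * t * t)


def cie_xyz_cmf(wavelengths_nm: np.ndarray) -> np.ndarray:
    """CIE 1931 2° x̄, ȳ, z̄ at the given wavelengths (shape (n, 3))."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = (
        0.362 * _lobe(wl, 442.0, 0.0624, 0.0374)
        + 1.056 * _lobe(wl, 599.8, 0.0264, 0.0323)
        - 0.065 * _lobe(wl, 501.1, 0.0490, 0.0382)
    )
    y = 0.821 * _lobe(wl, 568.8, 0.0213, 0.0247) + 0.286 * _lobe(
        wl, 530.9, 0.0613, 0.0322
    )
    z = 1.217 * _lobe(wl, 437.0, 0.0845, 0.0278) + 0.681 * _lobe(
        wl, 459.0, 0.0385, 0.0725
    )
    return np.stack([x, y, z], axis=-1)


# linear sRGB from XYZ (IEC 61966-2-1, D65)
_XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def illuminant_spd(name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Spectral power of a named illuminant on the given grid.

    ``"E"`` (equal energy, default elsewhere) is flat; ``"D65"`` is
    approximated by a 6504 K Planck radiator, adequate for swatch rendering.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if name.upper() == "E":
        return np.ones_like(wl)
    if name.upper() == "D65":
        # Planck's law at the D65 correlated color temperature
        h, c, kb, T = 6.626e-34, 2.998e8, 1.381e-23, 6504.0
        lam = wl * 1e-9
        spd = 1.0 / (lam**5 * (np.exp(h * c / (lam * kb * T)) - 1.0))
        return spd / spd.max()
    raise ValueError(f"unknown illuminant {name!r} (use 'E' or 'D65')")


def _gamma_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.clip(linear, 0.0, None)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1 / 2.4) - 0.055,
    )


@dataclass(frozen=True)
class ColorRGB:
    """An RGB triple in [0, 1] with a color-space tag."""

    r: float
    g: float
    b: float
    space: str = "sRGB"  # "sRGB" (gamma-encoded) or "linear"

    def __post_init__(self) -> None:
        for v in (self.r, self.g, self.b):
            if not 0.0 <= v <= 1.0:
                raise ValueError("RGB channels must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)

    def as_8bit(self) -> tuple[int, int, int]:
        return tuple(int(round(v * 255)) for v in self.as_tuple())


def spectrum_to_linear_rgb(
    wavelengths_nm: np.ndarray,
    spectrum: np.ndarray,
    illuminant: str = "E",
) -> np.ndarray:
    """Integrate spectrum × illuminant against the CMFs to linear RGB.

    Normalized so a flat unit spectrum yields (1, 1, 1).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    if wl.size < 2:
        raise ValueError("spectrum needs at least two wavelength points")
    if wl.max() < 380 or wl.min() > 750:
        raise ValueError("spectrum support does not overlap the visible band")
    cmf = cie_xyz_cmf(wl)
    spd = illuminant_spd(illuminant, wl)
    xyz = np.trapezoid(cmf * (spd * spec)[:, None], wl, axis=0)
    xyz_white = np.trapezoid(cmf * spd[:, None], wl, axis=0)
    rgb = _XYZ_TO_RGB @ xyz
    rgb_white = _XYZ_TO_RGB @ xyz_white
    return rgb / rgb_white


def linear_to_color(rgb_linear: np.ndarray, clip_notice: bool = True) -> ColorRGB:
    rgb = np.asarray(rgb_linear, dtype=float)
    if clip_notice and ((rgb < 0).any() or (rgb > 1).any()):
        logger.info("RGB %s out of sRGB gamut; clipping", rgb)
    encoded = _gamma_encode(np.clip(rgb, 0.0, 1.0))
    return ColorRGB(*np.clip(encoded, 0.0, 1.0), space="sRGB")
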