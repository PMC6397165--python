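"""Multilayer thin-film interference model of chromatophore iridescence.

The sheath cells wrapping the pigment cell form alternating layers of
cytoplasm (thickness ``d_a``, index ``n_a``) and membrane (``d_b``,
``n_b``).  Such a stack reflects constructively at wavelengths satisfying
the two-beam interference condition

    m·λ = 2 (n_a d_a cosθ_a + n_b d_b cosθ_b)

with internal angles from Snell's law.  The full-wave reflectance is
computed with the standard characteristic-matrix (transfer-matrix)
recursion, which the two-beam condition approximates at low index contrast.

When the chromatophore expands into a flattened disc, volume conservation
thins the cytoplasm layers, shifting the constructive wavelength toward the
blue; relaxation thickens them back toward the red.  This is the mechanism
the model quantifies.

Measured layer statistics from electron micrographs: cytoplasm 116 ± 102 nm
(n = 292), membrane 71 ± 14 nm (n = 237).  Refractive indices default to
standard values for cytoplasm (1.33) and lipid bilayer membranes (1.46);
the stack is embedded in tissue, so ambient and substrate default to the
cytoplasm index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from chromatophore.color import ColorRGB, linear_to_color, spectrum_to_linear_rgb

#: study defaults (nm): cytoplasm layer mean/sd, membrane layer mean/sd
CYTOPLASM_MEAN_NM = 116.0
CYTOPLASM_SD_NM = 102.0
MEMBRANE_MEAN_NM = 71.0
MEMBRANE_SD_NM = 14.0
N_CYTOPLASM = 1.33
N_MEMBRANE = 1.46
#: lower truncation bound for sampled thicknesses (sd 102 > mean 116
#: would otherwise produce non-physical negative thicknesses)
THICKNESS_FLOOR_NM = 10.0

DEFAULT_GRID_NM = np.arange(380.0, 751.0, 1.0)

Polarization = Literal["s", "p", "unpolarized"]


@dataclass(frozen=True)
class Layer:
    """One optical layer: physical thickness (nm) and refractive index."""

    thickness_nm: float
    index: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.thickness_nm <= 0:
            raise ValueError("layer thickness must be positive")
        if self.index < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class LayerStack:
    """An ordered stack of layers between ambient and substrate media."""

    layers: tuple[Layer, ...]
    n_ambient: float = N_CYTOPLASM
    n_substrate: float = N_CYTOPLASM

    @classmethod
    def alternating(
        cls,
        d_a: float | Sequence[float],
        d_b: float | Sequence[float],
        n_pairs: int,
        n_a: float = N_CYTOPLASM,
        n_b: float = N_MEMBRANE,
        n_ambient: float | None = None,
        n_substrate: float | None = None,
    ) -> "LayerStack":
        """Build an a/b/a/b... stack of ``n_pairs`` cytoplasm/membrane pairs.

        ``d_a``/``d_b`` may be scalars (uniform stack) or per-pair sequences.
        """
        if n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        da = np.broadcast_to(np.asarray(d_a, dtype=float), (n_pairs,))
        db = np.broadcast_to(np.asarray(d_b, dtype=float), (n_pairs,))
        layers = []
        for i in range(n_pairs):
            layers.append(Layer(float(da[i]), n_a, "a"))
            layers.append(Layer(float(db[i]), n_b, "b"))
        return cls(
            layers=tuple(layers),
            n_ambient=n_ambient if n_ambient is not None else n_a,
            n_substrate=n_substrate if n_substrate is not None else n_a,
        )

    def thicknesses(self, label: str | None = None) -> np.ndarray:
        return np.array(
            [
                l.thickness_nm
                for l in self.layers
                if label is None or l.label == label
            ]
        )


@dataclass(frozen=True)
class ThicknessDistribution:
    """Truncated-normal layer-thickness model (nm)."""

    mean: float
    sd: float
    lower_bound: float = THICKNESS_FLOOR_NM

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.lower_bound <= 0:
            raise ValueError("lower truncation bound must be positive")
        if self.sd > 0 and self.lower_bound > self.mean + 5 * self.sd:
            raise ValueError(
                "truncation bound lies more than 5 sd above the mean; "
                "the truncated distribution is numerically empty"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(self.mean))
        a = (self.lower_bound - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )

    def truncated_mean(self) -> float:
        """Closed-form mean of the truncated normal."""
        if self.sd == 0:
            return self.mean
        a = (self.lower_bound - self.mean) / self.sd
        return float(stats.truncnorm.mean(a, np.inf, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance R(λ) on a strictly increasing wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if r.shape != wl.shape:
            raise ValueError("reflectance and wavelength shapes differ")
        if (r < -1e-12).any() or (r > 1 + 1e-12).any():
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", np.clip(r, 0.0, 1.0))


def _internal_cos(n0: float, theta0_rad: float, n: np.ndarray) -> np.ndarray:
    """cosθ inside each medium via Snell's law; complex under TIR."""
    sin2 = (n0 * np.sin(theta0_rad) / n) ** 2
    return np.sqrt(1.0 - sin2.astype(complex))


def ideal_lambda_max(
    n_a: float,
    d_a: float,
    n_b: float,
    d_b: float,
    theta0_deg: float = 0.0,
    order: int = 1,
    n_ambient: float | None = None,
) -> float:
    """m-th order constructive wavelength of the two-beam condition (nm).

    ``m·λ = 2 (n_a d_a cosθ_a + n_b d_b cosθ_b)`` with internal angles from
    Snell's law out of the ambient medium (default: the cytoplasm itself).
    """
    if order < 1:
        raise ValueError("interference order must be >= 1")
    if not 0 <= theta0_deg < 90:
        raise ValueError("incidence angle must lie in [0°, 90°)")
    if min(n_a, n_b) < 1:
        raise ValueError("refractive indices must be >= 1")
    n0 = n_ambient if n_ambient is not None else n_a
    th0 = np.deg2rad(theta0_deg)
    cos_a, cos_b = _internal_cos(n0, th0, np.array([n_a, n_b]))
    if abs(cos_a.imag) > 1e-12 or abs(cos_b.imag) > 1e-12:
        raise ValueError("total internal reflection: no propagating order")
    return float(2.0 * (n_a * d_a * cos_a.real + n_b * d_b * cos_b.real) / order)


def _tmm_single_pol(
    stack: LayerStack,
    wavelengths: np.ndarray,
    theta0_rad: float,
    pol: str,
) -> tuple[np.ndarray, np.ndarray]:
    n0, ns = stack.n_ambient, stack.n_substrate
    cos0 = np.cos(theta0_rad)
    cos_sub = _internal_cos(n0, theta0_rad, np.array([ns]))[0]
    eta0 = n0 * cos0 if pol == "s" else n0 / cos0
    eta_sub = ns * cos_sub if pol == "s" else ns / cos_sub

    nwl = wavelengths.size
    # characteristic matrix product, vectorized over wavelength
    B = np.ones(nwl, dtype=complex)
    C = np.full(nwl, eta_sub, dtype=complex)
    for layer in reversed(stack.layers):
        nj = layer.index
        cosj = _internal_cos(n0, theta0_rad, np.array([nj]))[0]
        delta = 2.0 * np.pi * nj * layer.thickness_nm * cosj / wavelengths
        eta = nj * cosj if pol == "s" else nj / cosj
        cd, sd = np.cos(delta), np.sin(delta)
        B, C = cd * B + 1j * sd / eta * C, 1j * eta * sd * B + cd * C

    denom = eta0 * B + C
    r = (eta0 * B - C) / denom
    R = np.abs(r) ** 2
    T = 4.0 * eta0 * np.real(eta_sub) / np.abs(denom) ** 2
    return R, T


def transfer_matrix_reflectance(
    stack: LayerStack,
    wavelengths_nm: np.ndarray | Sequence[float] = DEFAULT_GRID_NM,
    theta0_deg: float = 0.0,
    polarization: Polarization = "unpolarized",
) -> ReflectanceSpectrum:
    """Full-wave reflectance of the stack by the characteristic-matrix method.

    An empty stack returns the bare ambient/substrate Fresnel result.  For
    lossless (real-index) stacks, R + T = 1 to machine precision.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if (wl <= 0).any():
        raise ValueError("wavelengths must be positive")
    if not 0 <= theta0_deg < 90:
        raise ValueError("incidence angle must lie in [0°, 90°)")
    th0 = np.deg2rad(theta0_deg)
    if polarization == "unpolarized":
        Rs, Ts = _tmm_single_pol(stack, wl, th0, "s")
        Rp, Tp = _tmm_single_pol(stack, wl, th0, "p")
        R, T = 0.5 * (Rs + Rp), 0.5 * (Ts + Tp)
    elif polarization in ("s", "p"):
        R, T = _tmm_single_pol(stack, wl, th0, polarization)
    else:
        raise ValueError(f"unknown polarization {polarization!r}")
    return ReflectanceSpectrum(wavelengths_nm=wl, reflectance=R, transmittance=T)


def sample_stack(
    dist_a: ThicknessDistribution,
    dist_b: ThicknessDistribution,
    n_pairs: int,
    n_a: float = N_CYTOPLASM,
    n_b: float = N_MEMBRANE,
    seed: int | np.random.Generator = 0,
) -> LayerStack:
    """Draw an alternating stack with truncated-normal layer thicknesses."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    da = dist_a.sample(n_pairs, rng)
    db = dist_b.sample(n_pairs, rng)
    return LayerStack.alternating(da, db, n_pairs, n_a=n_a, n_b=n_b)


def expand_layers(
    stack: LayerStack, areal_factor: float, membrane_fixed: bool = False
) -> LayerStack:
    """Thin the layers of an areally expanding stack.

    A layer spreading over ``areal_factor`` times its area conserves volume,
    so each thickness is divided by the factor.  ``membrane_fixed=True``
    holds membrane ("b") layers at their native thickness, modeling bilayers
    that fold out rather than stretch.
    """
    if areal_factor < 1:
        raise ValueError("areal expansion factor must be >= 1")
    new_layers = tuple(
        layer
        if (membrane_fixed and layer.label == "b")
        else replace(layer, thickness_nm=layer.thickness_nm / areal_factor)
        for layer in stack.layers
    )
    return replace(stack, layers=new_layers)


def lambda_peak(spectrum: ReflectanceSpectrum) -> float:
    """Wavelength of maximum reflectance (nm); ties resolve to the lowest."""
    r = spectrum.reflectance
    if not (r > 0).any():
        raise ValueError("all-zero spectrum has no peak")
    return float(spectrum.wavelengths_nm[int(np.argmax(r))])


def spectrum_to_srgb(
    spectrum: ReflectanceSpectrum,
    illuminant: str = "E",
    observer: str = "CIE1931-2deg",
) -> ColorRGB:
    """Render the perceived color of a reflectance spectrum.

    Spectrum × illuminant is integrated against the CIE 1931 2° color
    matching functions, converted to linear sRGB relative to the perfect
    diffuser, gamma-encoded, and gamut-clipped (with a log notice).
    """
    if observer not in ("CIE1931-2deg", "CIE1931"):
        raise ValueError(f"unsupported observer {observer!r}")
    rgb_lin = spectrum_to_linear_rgb(
        spectrum.wavelengths_nm, spectrum.reflectance, illuminant
    )
    return linear_to_color(rgb_lin)
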