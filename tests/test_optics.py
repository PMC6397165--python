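"""Thin-film interference: analytic oracles and physical invariants."""

import numpy as np
import pytest

from chromatophore.color import ColorRGB
from chromatophore.optics import (
    DEFAULT_GRID_NM,
    Layer,
    LayerStack,
    ReflectanceSpectrum,
    ThicknessDistribution,
    expand_layers,
    ideal_lambda_max,
    lambda_peak,
    sample_stack,
    spectrum_to_srgb,
    transfer_matrix_reflectance,
)


def quarter_wave_reflectance(n0, n_h, n_l, n_sub, n_pairs):
    """Closed-form admittance of an (HL)^N quarter-wave stack at design λ."""
    y = (n_h / n_l) ** (2 * n_pairs) * n_sub
    return ((n0 - y) / (n0 + y)) ** 2


class TestIdealLambdaMax:
    def test_unit_index_normal_incidence(self):
        assert ideal_lambda_max(1.0, 100, 1.0, 150, n_ambient=1.0) == pytest.approx(500.0)

    def test_second_order_halves(self):
        assert ideal_lambda_max(1.0, 100, 1.0, 150, order=2, n_ambient=1.0) == \
            pytest.approx(250.0)

    def test_monotone_in_thickness_and_index(self):
        base = dict(n_a=1.33, d_a=116.0, n_b=1.46, d_b=71.0)
        lam0 = ideal_lambda_max(**base)
        for key, bump in [("d_a", 10), ("d_b", 10), ("n_a", 0.05), ("n_b", 0.05)]:
            kwargs = dict(base)
            kwargs[key] += bump
            assert ideal_lambda_max(**kwargs) > lam0

    def test_oblique_incidence_shortens_wavelength(self):
        lam0 = ideal_lambda_max(1.33, 116, 1.46, 71, theta0_deg=0)
        lam45 = ideal_lambda_max(1.33, 116, 1.46, 71, theta0_deg=45)
        assert lam45 < lam0

    def test_total_internal_reflection_rejected(self):
        with pytest.raises(ValueError, match="internal reflection"):
            ideal_lambda_max(1.0, 100, 1.0, 100, theta0_deg=60, n_ambient=2.0)


class TestTransferMatrix:
    def test_bare_interface_fresnel(self):
        stack = LayerStack(layers=(), n_ambient=1.0, n_substrate=1.5)
        sp = transfer_matrix_reflectance(stack)
        assert np.allclose(sp.reflectance, 0.04, atol=1e-12)

    def test_matched_media_reflect_nothing(self):
        stack = LayerStack(
            layers=(Layer(100.0, 1.4), Layer(50.0, 1.4)),
            n_ambient=1.4,
            n_substrate=1.4,
        )
        sp = transfer_matrix_reflectance(stack)
        assert np.allclose(sp.reflectance, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n_pairs", [1, 4, 10])
    def test_quarter_wave_stack_matches_closed_form(self, n_pairs):
        lam0, n_h, n_l, n0, ns = 550.0, 2.3, 1.38, 1.0, 1.52
        layers = []
        for _ in range(n_pairs):
            layers.append(Layer(lam0 / (4 * n_h), n_h))
            layers.append(Layer(lam0 / (4 * n_l), n_l))
        stack = LayerStack(tuple(layers), n_ambient=n0, n_substrate=ns)
        sp = transfer_matrix_reflectance(stack, wavelengths_nm=np.array([lam0]))
        expect = quarter_wave_reflectance(n0, n_h, n_l, ns, n_pairs)
        assert sp.reflectance[0] == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("theta", [0.0, 25.0, 50.0])
    @pytest.mark.parametrize("pol", ["s", "p", "unpolarized"])
    def test_energy_conservation_lossless(self, rng, theta, pol):
        layers = tuple(
            Layer(float(rng.uniform(20, 300)), float(rng.uniform(1.2, 1.8)))
            for _ in range(12)
        )
        stack = LayerStack(layers, n_ambient=1.33, n_substrate=1.40)
        sp = transfer_matrix_reflectance(stack, theta0_deg=theta, polarization=pol)
        assert np.allclose(sp.reflectance + sp.transmittance, 1.0, atol=1e-9)

    def test_reciprocity_at_normal_incidence(self, rng):
        layers = tuple(
            Layer(float(rng.uniform(30, 200)), float(rng.uniform(1.2, 1.9)))
            for _ in range(7)
        )
        fwd = LayerStack(layers, n_ambient=1.0, n_substrate=1.5)
        rev = LayerStack(tuple(reversed(layers)), n_ambient=1.5, n_substrate=1.0)
        r_fwd = transfer_matrix_reflectance(fwd).reflectance
        r_rev = transfer_matrix_reflectance(rev).reflectance
        assert np.allclose(r_fwd, r_rev, atol=1e-10)

    def test_two_beam_agrees_with_full_wave_at_low_contrast(self):
        # index contrast 0.13, 12 pairs: peak within 5 nm of two-beam λmax
        stack = LayerStack.alternating(116.0, 71.0, 12)
        lam_ideal = ideal_lambda_max(1.33, 116.0, 1.46, 71.0)
        grid = np.arange(300.0, 801.0, 0.5)
        sp = transfer_matrix_reflectance(stack, wavelengths_nm=grid)
        assert abs(lambda_peak(sp) - lam_ideal) <= 5.0

    def test_zero_thickness_layer_rejected(self):
        with pytest.raises(ValueError):
            Layer(0.0, 1.4)


class TestSampleStack:
    def test_sd_zero_gives_constant_layers(self):
        stack = sample_stack(
            ThicknessDistribution(116.0, 0.0), ThicknessDistribution(71.0, 0.0), 5
        )
        assert np.allclose(stack.thicknesses("a"), 116.0)
        assert np.allclose(stack.thicknesses("b"), 71.0)

    def test_large_sample_mean_matches_truncated_normal_moment(self):
        dist = ThicknessDistribution(116.0, 102.0, lower_bound=10.0)
        draws = dist.sample(10_000, np.random.default_rng(11))
        expect = dist.truncated_mean()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expect) < 3 * se
        assert (draws >= 10.0).all()

    def test_fixed_seed_reproducible(self):
        d_a, d_b = ThicknessDistribution(116, 102), ThicknessDistribution(71, 14)
        s1 = sample_stack(d_a, d_b, 8, seed=42)
        s2 = sample_stack(d_a, d_b, 8, seed=42)
        assert s1 == s2

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ValueError, match="truncat"):
            ThicknessDistribution(10.0, 1.0, lower_bound=100.0)


class TestExpandLayers:
    def test_identity_at_factor_one(self):
        stack = LayerStack.alternating(116.0, 71.0, 3)
        assert expand_layers(stack, 1.0) == stack

    def test_volume_conservation_halves_thickness(self):
        stack = LayerStack.alternating(116.0, 71.0, 1)
        out = expand_layers(stack, 2.0)
        assert out.thicknesses("a")[0] == pytest.approx(58.0)

    def test_membrane_fixed_flag(self):
        stack = LayerStack.alternating(116.0, 71.0, 2)
        out = expand_layers(stack, 4.0, membrane_fixed=True)
        assert np.allclose(out.thicknesses("b"), 71.0)
        assert np.allclose(out.thicknesses("a"), 29.0)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            expand_layers(LayerStack.alternating(116, 71, 1), 0.5)

    def test_blue_shift_monotone_in_expansion(self):
        """λmax strictly decreases as the stack expands (the model's
        blue-shift-on-actuation prediction)."""
        lams = [
            ideal_lambda_max(1.33, 116.0 / f, 1.46, 71.0 / f)
            for f in np.linspace(1.0, 15.0, 25)
        ]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_blue_shift_in_full_wave_peak(self):
        base = LayerStack.alternating(116.0, 71.0, 10)
        grid = np.arange(200.0, 801.0, 0.5)
        peaks = []
        for f in [1.0, 1.2, 1.5, 1.8, 2.2]:
            sp = transfer_matrix_reflectance(expand_layers(base, f), grid)
            peaks.append(lambda_peak(sp))
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))


class TestColorRendering:
    def test_flat_spectrum_is_white(self):
        sp = ReflectanceSpectrum(DEFAULT_GRID_NM, np.ones_like(DEFAULT_GRID_NM))
        c = spectrum_to_srgb(sp)
        assert c.r == pytest.approx(c.g, abs=1e-6)
        assert c.g == pytest.approx(c.b, abs=1e-6)
        assert c.r > 0.99

    def test_zero_spectrum_is_black(self):
        sp = ReflectanceSpectrum(DEFAULT_GRID_NM, np.zeros_like(DEFAULT_GRID_NM))
        assert spectrum_to_srgb(sp).as_tuple() == (0.0, 0.0, 0.0)

    def test_green_band_makes_green_dominant(self):
        r = np.exp(-0.5 * ((DEFAULT_GRID_NM - 550.0) / 10.0) ** 2)
        c = spectrum_to_srgb(ReflectanceSpectrum(DEFAULT_GRID_NM, r))
        assert c.g == max(c.as_tuple())

    def test_out_of_range_channel_rejected(self):
        with pytest.raises(ValueError):
            ColorRGB(1.2, 0.0, 0.0)


class TestLambdaPeak:
    def test_single_peak(self):
        wl = np.arange(380.0, 751.0)
        r = np.exp(-0.5 * ((wl - 520.0) / 5.0) ** 2)
        assert lambda_peak(ReflectanceSpectrum(wl, r)) == 520.0

    def test_plateau_tie_takes_left_edge(self):
        wl = np.arange(380.0, 751.0)
        r = np.zeros_like(wl)
        r[100:110] = 0.5
        assert lambda_peak(ReflectanceSpectrum(wl, r)) == wl[100]

    def test_random_spectrum_equals_linear_scan(self, rng):
        wl = np.arange(380.0, 751.0)
        r = rng.uniform(0, 1, size=wl.size)
        sp = ReflectanceSpectrum(wl, r)
        brute = wl[min(range(wl.size), key=lambda i: (-r[i], wl[i]))]
        assert lambda_peak(sp) == brute

    def test_all_zero_rejected(self):
        wl = np.arange(380.0, 751.0)
        with pytest.raises(ValueError):
            lambda_peak(ReflectanceSpectrum(wl, np.zeros_like(wl)))
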