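"""Powder simulation: resonance physics, lineshapes, pseudo-modulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fesepr import (
    CONST,
    GTensor,
    InstrumentConfig,
    SpeciesModel,
    Spectrum,
    classify_symmetry,
    effective_g,
    powder_spectrum,
    pseudo_modulate,
    resonance_field,
)
from fesepr.spin_sim import octant_grid


g_values = st.floats(min_value=1.5, max_value=2.5)


class TestEffectiveG:
    @pytest.mark.parametrize(
        "g, theta, phi, expected",
        [
            ((2.045, 1.926, 1.896), 0.0, 0.0, 1.896),  # along g3 axis
            ((2.045, 1.926, 1.896), np.pi / 2, 0.0, 2.045),  # along g1 axis
            ((2.045, 1.926, 1.896), np.pi / 2, np.pi / 2, 1.926),  # along g2
            ((2.000, 2.000, 2.000), 0.7, 1.3, 2.000),  # isotropic limit
        ],
    )
    def test_principal_axes_and_isotropic(self, g, theta, phi, expected):
        assert effective_g(GTensor(*g), theta, phi) == pytest.approx(expected, abs=1e-12)

    @given(g1=g_values, g2=g_values, g3=g_values)
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_extreme_principal_values(self, g1, g2, g3):
        g = GTensor(g1, g2, g3)
        theta, phi, _ = octant_grid(25, 25)
        ge = effective_g(g, theta, phi)
        assert np.all(ge >= g.g3 - 1e-12)
        assert np.all(ge <= g.g1 + 1e-12)

    def test_descending_storage_and_validation(self):
        g = GTensor(1.896, 2.045, 1.926)
        assert (g.g1, g.g2, g.g3) == (2.045, 1.926, 1.896)
        with pytest.raises(ValueError):
            GTensor(2.0, -1.0, 1.9)


class TestResonanceField:
    def test_free_electron_x_band(self):
        # closed form h*nu/(g*mu_B) with CODATA constants
        assert resonance_field(2.0023, 9.7) == pytest.approx(346.1, abs=0.05)

    def test_g1_q_band(self):
        assert resonance_field(2.045, 34.0) == pytest.approx(1187.9, abs=0.05)

    def test_linear_in_frequency_and_g_product_constant(self):
        b1 = resonance_field(2.01, 9.7)
        assert resonance_field(2.01, 19.4) == pytest.approx(2 * b1, rel=1e-12)
        for g in (1.8, 2.0, 2.2):
            assert g * resonance_field(g, 9.7) == pytest.approx(
                2.01 * b1, rel=1e-12)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            resonance_field(0.0, 9.7)
        with pytest.raises(ValueError):
            resonance_field(2.0, -1.0)


class TestPowderSpectrum:
    def test_axial_absorption_edges(self, x_band_abs):
        # principal-g resonance fields bound the powder envelope
        sp = SpeciesModel("ax", GTensor(2.040, 1.910, 1.910),
                          g_strain=(0.001, 0.001, 0.001), residual_linewidth=0.3)
        spec = powder_spectrum(sp, x_band_abs.replace(n_points=4096), 64, 64)
        dy = np.gradient(spec.intensity, spec.field_axis)
        lo = spec.field_axis < 350  # g_parallel shoulder is the weak low-field step
        rising_edge = spec.field_axis[np.argmax(np.where(lo, dy, -np.inf))]
        falling_edge = spec.field_axis[np.argmin(dy)]  # g_perp divergence
        assert rising_edge == pytest.approx(339.7, abs=0.5)
        assert falling_edge == pytest.approx(362.9, abs=0.5)

    def test_isotropic_single_symmetric_line(self):
        sp = SpeciesModel("iso", GTensor(2.0, 2.0, 2.0), residual_linewidth=1.0)
        inst = InstrumentConfig(9.7, 320, 375, 2048, detection_mode="absorption")
        spec = powder_spectrum(sp, inst)
        center = spec.field_axis[np.argmax(spec.intensity)]
        assert center == pytest.approx(resonance_field(2.0, 9.7), abs=0.1)
        # symmetry about the centre
        b0 = resonance_field(2.0, 9.7)
        left = np.interp(b0 - 3.0, spec.field_axis, spec.intensity)
        right = np.interp(b0 + 3.0, spec.field_axis, spec.intensity)
        assert left == pytest.approx(right, rel=5e-3)

    def test_non_negative_and_unit_integral(self, rhombic_species, q_band_abs):
        spec = powder_spectrum(rhombic_species, q_band_abs)
        assert np.all(spec.intensity >= 0)
        assert spec.integral() == pytest.approx(1.0, rel=1e-9)

    def test_orientation_grid_convergence(self, rhombic_species, q_band_abs):
        coarse = powder_spectrum(rhombic_species, q_band_abs, 32, 32)
        fine = powder_spectrum(rhombic_species, q_band_abs, 64, 64)
        scale = np.abs(fine.intensity).max()
        assert np.abs(coarse.intensity - fine.intensity).max() / scale < 1e-3

    def test_integral_stable_under_resolution_and_linewidth(self, q_band_abs):
        sp = SpeciesModel("s", GTensor(2.05, 1.92, 1.85), g_strain=(0.01,) * 3,
                          residual_linewidth=1.0)
        a1 = powder_spectrum(sp, q_band_abs).integral()
        a2 = powder_spectrum(sp, q_band_abs.replace(n_points=2048)).integral()
        a3 = powder_spectrum(sp.replace(residual_linewidth=2.5), q_band_abs).integral()
        assert abs(a2 - a1) / a1 < 1e-3
        assert abs(a3 - a1) / a1 < 1e-3

    def test_strain_broadening_increases_second_moment(self, q_band_abs):
        base = SpeciesModel("s", GTensor(2.05, 1.92, 1.85), g_strain=(0.005,) * 3,
                            residual_linewidth=0.8)

        def second_moment(sp):
            spec = powder_spectrum(sp, q_band_abs)
            b, y = spec.field_axis, spec.intensity
            mu = np.trapezoid(b * y, b)
            return np.trapezoid((b - mu) ** 2 * y, b)

        m0 = second_moment(base)
        for axis in range(3):
            strain = list(base.g_strain)
            strain[axis] *= 3
            assert second_moment(base.replace(g_strain=tuple(strain))) > m0

    def test_window_warning_and_error(self):
        sp = SpeciesModel("s", GTensor(2.05, 1.92, 1.85), residual_linewidth=1.0)
        tight = InstrumentConfig(34.0, 1180, 1260, 512, detection_mode="absorption")
        with pytest.warns(UserWarning, match="field window"):
            powder_spectrum(sp, tight)
        far = InstrumentConfig(34.0, 100, 200, 256, detection_mode="absorption")
        with pytest.raises(ValueError, match="excludes all resonance"):
            with pytest.warns(UserWarning):
                powder_spectrum(sp, far)

    def test_frequency_invariance_of_turning_point_g(self, narrow_species):
        """Reading g back at the spectral extrema gives the same values at
        9.7 and 34 GHz — the multi-frequency consistency check."""
        g_true = narrow_species.g.values
        g_read = {}
        for nu in (9.7, 34.0):
            b_lo = resonance_field(g_true[0], nu) - 15
            b_hi = resonance_field(g_true[2], nu) + 15
            inst = InstrumentConfig(nu, b_lo, b_hi, 8192, detection_mode="absorption")
            spec = powder_spectrum(narrow_species, inst, 96, 96)
            b, y = spec.field_axis, spec.intensity
            dy = np.gradient(y, b)
            reads = []
            # each turning point searched near its own principal resonance:
            # rising inflection (g1 edge), absorption maximum (g2),
            # falling inflection (g3 edge)
            for g_i, score in ((g_true[0], dy), (g_true[1], y), (g_true[2], -dy)):
                win = np.abs(b - resonance_field(g_i, nu)) < 6.0
                b_tp = b[np.argmax(np.where(win, score, -np.inf))]
                reads.append(CONST.h * nu * 1e9 / (b_tp * 1e-3 * CONST.mu_B))
            g_read[nu] = np.array(reads)
        assert np.abs(g_read[9.7] - g_read[34.0]).max() < 1e-3


class TestPseudoModulation:
    def _gaussian_spec(self, sigma=2.0, n=2048):
        inst = InstrumentConfig(9.7, 300, 400, n, detection_mode="absorption")
        b = inst.field_axis
        return Spectrum(b, np.exp(-0.5 * ((b - 350) / sigma) ** 2), inst)

    def test_zero_amplitude_gives_zero_signal(self):
        spec = self._gaussian_spec()
        out = pseudo_modulate(spec, 0.0)
        assert np.all(out.intensity == 0)

    def test_extrema_at_plus_minus_sigma(self):
        spec = self._gaussian_spec(sigma=2.0)
        out = pseudo_modulate(spec, 0.1)
        b = out.field_axis
        assert b[np.argmax(out.intensity)] == pytest.approx(348.0, abs=0.05)
        assert b[np.argmin(out.intensity)] == pytest.approx(352.0, abs=0.05)

    def test_linear_in_amplitude_when_small(self):
        spec = self._gaussian_spec()
        a1 = pseudo_modulate(spec, 0.1).intensity
        a2 = pseudo_modulate(spec, 0.2).intensity
        core = np.abs(a2) > 0.05 * np.abs(a2).max()
        assert np.allclose(a1[core] / a2[core], 0.5, atol=0.01)

    def test_derivative_limit(self):
        # amplitude = linewidth/100 reproduces amplitude * dS/dB
        sigma = 2.0
        spec = self._gaussian_spec(sigma=sigma, n=4096)
        a = sigma / 100
        out = pseudo_modulate(spec, a)
        deriv = np.gradient(spec.intensity, spec.field_axis)
        err = np.abs(out.intensity / a - deriv).max() / np.abs(deriv).max()
        assert err < 1e-3

    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError):
            pseudo_modulate(self._gaussian_spec(), -1.0)


class TestClassifySymmetry:
    @pytest.mark.parametrize(
        "g, expected",
        [
            ((2.040, 1.910, 1.910), "axial"),
            ((2.050, 1.915, 1.852), "rhombic"),
            ((2.000, 2.000, 2.000), "isotropic"),
            ((2.054, 1.921, 1.848), "rhombic"),
            ((2.004, 2.004, 1.900), "axial"),  # degenerate upper pair
        ],
    )
    def test_symmetry_classes(self, g, expected):
        assert classify_symmetry(GTensor(*g)) == expected

    def test_tolerance_widens_classes(self):
        g = GTensor(2.02, 2.00, 1.98)
        assert classify_symmetry(g) == "rhombic"
        assert classify_symmetry(g, tol=0.05) == "isotropic"


class TestSpectrumContainer:
    def test_rejects_non_uniform_axis(self, x_band):
        b = np.array([1.0, 2.0, 4.0, 8.0])
        with pytest.raises(ValueError, match="uniform"):
            Spectrum(b, np.zeros(4), x_band)

    def test_rejects_length_mismatch(self, x_band):
        with pytest.raises(ValueError):
            Spectrum(np.linspace(0, 1, 5), np.zeros(4), x_band)
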