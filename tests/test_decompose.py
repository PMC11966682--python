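"""Spectral unmixing: NNLS weights, variable-projection refinement, global fits."""

import itertools

import numpy as np
import pytest

from fesepr import (
    GTensor,
    NoiseModel,
    SpeciesModel,
    Spectrum,
    fit_weights,
    generate_spectrum,
    global_fit,
    model_selection,
    powder_spectrum,
    refine_species,
    simulate_mixture,
)
from fesepr.decompose import CollinearityWarning
from fesepr.spin_sim import apply_detection


class TestSimulateMixture:
    def test_single_species_identity(self, axial_species, q_band_abs):
        mix = simulate_mixture([axial_species], [1.0], q_band_abs)
        single = powder_spectrum(axial_species, q_band_abs)
        np.testing.assert_allclose(mix.intensity, single.intensity, rtol=1e-12)

    def test_pointwise_linearity(self, axial_species, rhombic_species, q_band):
        mix = simulate_mixture([axial_species, rhombic_species], [0.5, 0.5], q_band)
        a = simulate_mixture([axial_species], [1.0], q_band)
        r = simulate_mixture([rhombic_species], [1.0], q_band)
        np.testing.assert_allclose(mix.intensity,
                                   0.5 * (a.intensity + r.intensity), atol=1e-14)

    def test_zero_weights_zero_spectrum(self, axial_species, q_band):
        mix = simulate_mixture([axial_species], [0.0], q_band)
        assert np.all(mix.intensity == 0)

    def test_input_validation(self, axial_species, q_band):
        with pytest.raises(ValueError):
            simulate_mixture([axial_species], [0.5, 0.5], q_band)
        with pytest.raises(ValueError):
            simulate_mixture([axial_species], [-0.1], q_band)


class TestFitWeights:
    def test_noiseless_one_to_two_mixture(self, axial_species, rhombic_species, q_band):
        target = simulate_mixture([axial_species, rhombic_species], [1 / 3, 2 / 3],
                                  q_band)
        fr = fit_weights(target, [axial_species, rhombic_species])
        np.testing.assert_allclose(fr.mixture.normalized_weights, [0.333, 0.667],
                                   atol=0.01)

    def test_pure_species_identifiability(self, axial_species, rhombic_species, q_band):
        target = simulate_mixture([axial_species], [1.0], q_band)
        fr = fit_weights(target, [axial_species, rhombic_species])
        assert fr.mixture.normalized_weights[1] < 0.01

    def test_monte_carlo_weight_recovery_snr20(self, axial_species, rhombic_species,
                                               q_band):
        """Mean recovered weights within 0.05 of truth and RMSE <= 0.05 at
        SNR 20 over 100 noise realizations."""
        truth = np.array([1 / 3, 2 / 3])
        recov = []
        for seed in range(100):
            spec, _ = generate_spectrum([axial_species, rhombic_species], truth,
                                        q_band, NoiseModel(snr=20.0, seed=seed))
            fr = fit_weights(spec, [axial_species, rhombic_species])
            recov.append(fr.mixture.normalized_weights)
        recov = np.array(recov)
        assert np.abs(recov.mean(axis=0) - truth).max() < 0.05
        assert np.sqrt(((recov - truth) ** 2).mean()) <= 0.05

    def test_weights_always_non_negative(self, axial_species, rhombic_species, q_band):
        # target is pure noise: NNLS must still return physical weights
        rng = np.random.default_rng(7)
        target = Spectrum(q_band.field_axis, rng.normal(size=q_band.n_points), q_band)
        fr = fit_weights(target, [axial_species, rhombic_species], baseline_order=1)
        assert np.all(fr.mixture.weights >= 0)

    def test_nnls_matches_lattice_search_oracle(self, presets, q_band):
        """NNLS solution within one 0.05 lattice step of exhaustive search."""
        species = [presets["axial-A"], presets["rhombic-R"], presets["Q-band FID"]]
        truth = np.array([0.2, 0.5, 0.3])
        target = simulate_mixture(species, truth, q_band)
        fr = fit_weights(target, species)

        cols = np.column_stack([simulate_mixture([sp], [1.0], q_band).intensity
                                for sp in species])
        lattice = np.arange(0.0, 1.0001, 0.05)
        best, best_rss = None, np.inf
        for w in itertools.product(lattice, repeat=3):
            rss = np.sum((cols @ np.array(w) - target.intensity) ** 2)
            if rss < best_rss:
                best, best_rss = np.array(w), rss
        assert np.abs(fr.mixture.weights - best).max() <= 0.05 + 1e-9

    def test_masking_silent_region_leaves_weights(self, axial_species,
                                                  rhombic_species, q_band):
        target = simulate_mixture([axial_species, rhombic_species], [0.4, 0.6], q_band)
        fr0 = fit_weights(target, [axial_species, rhombic_species])
        # mask the first 20 mT, where neither species has intensity
        fr1 = fit_weights(target, [axial_species, rhombic_species],
                          mask=[(1120.0, 1140.0)])
        assert np.abs(fr0.mixture.weights - fr1.mixture.weights).max() < 1e-6

    def test_scaling_invariance_of_normalized_weights(self, axial_species,
                                                      rhombic_species, q_band):
        target = simulate_mixture([axial_species, rhombic_species], [0.3, 0.7], q_band)
        scaled = target.with_intensity(5.0 * target.intensity)
        fr = fit_weights(target, [axial_species, rhombic_species])
        frs = fit_weights(scaled, [axial_species, rhombic_species])
        np.testing.assert_allclose(frs.mixture.weights, 5.0 * fr.mixture.weights,
                                   rtol=1e-6)
        np.testing.assert_allclose(frs.mixture.normalized_weights,
                                   fr.mixture.normalized_weights, atol=1e-8)

    def test_collinear_species_flagged(self, axial_species, q_band):
        twin = axial_species.replace(name="twin")
        target = simulate_mixture([axial_species], [1.0], q_band)
        with pytest.warns(CollinearityWarning):
            fr = fit_weights(target, [axial_species, twin])
        assert fr.collinear

    def test_all_masked_is_error(self, axial_species, q_band):
        target = simulate_mixture([axial_species], [1.0], q_band)
        with pytest.raises(ValueError, match="mask"):
            fit_weights(target, [axial_species], mask=[(0.0, 5000.0)])


class TestRefineSpecies:
    def test_round_trip_from_perturbed_start(self, presets, x_band):
        truth = presets["X-band cw"]
        target = simulate_mixture([truth], [1.0], x_band)
        init = truth.replace(g=GTensor(2.050, 1.917, 1.903))
        fr = refine_species(target, [init], g_bounds=0.03, multistart=3, seed=0)
        assert np.abs(fr.refined_species[0].g.values - truth.g.values).max() < 1e-3
        assert fr.converged

    def test_init_at_truth_converges_immediately(self, presets, x_band):
        truth = presets["Q-band FID"]
        target = simulate_mixture([truth], [1.0], x_band)
        fr = refine_species(target, [truth], g_bounds=0.02, multistart=1)
        assert fr.residual_norm < 1e-8
        assert np.abs(fr.refined_species[0].g.values - truth.g.values).max() < 1e-6

    def test_bounds_excluding_truth_flags_boundary(self, presets, x_band):
        truth = presets["Q-band FID"]
        target = simulate_mixture([truth], [1.0], x_band)
        shifted = truth.replace(g=GTensor(2.060, 1.941, 1.911))
        fr = refine_species(target, [shifted], g_bounds=0.005, multistart=1)
        assert fr.at_boundary

    def test_missing_bounds_rejected(self, presets, x_band):
        truth = presets["Q-band FID"]
        target = simulate_mixture([truth], [1.0], x_band)
        with pytest.raises(ValueError, match="bounds"):
            refine_species(target, [truth], g_bounds={"Q-band FID.g1": (2.0, 2.1)})

    def test_monte_carlo_g_recovery_snr50(self, q_band):
        """g RMSE <= 2e-3 at SNR 50 on single-species refits (lean settings)."""
        truth = SpeciesModel("t", GTensor(2.050, 1.915, 1.852),
                             g_strain=(0.01,) * 3, residual_linewidth=1.0)
        init = truth.replace(g=GTensor(2.055, 1.910, 1.857))
        inst = q_band.replace(n_points=512)
        errs = []
        for seed in range(20):
            spec, _ = generate_spectrum([truth], [1.0], inst,
                                        NoiseModel(snr=50.0, seed=seed),
                                        n_theta=16, n_phi=16)
            fr = refine_species(spec, [init], g_bounds=0.02, multistart=1,
                                n_theta=16, n_phi=16, max_nfev=40)
            errs.append(fr.refined_species[0].g.values - truth.g.values)
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse <= 2e-3


class TestGlobalFit:
    def test_shared_g_recovered_across_frequencies(self, presets, x_band, q_band):
        truth = presets["Q-band ESE"]
        data = [simulate_mixture([truth], [1.0], inst) for inst in (x_band, q_band)]
        init = truth.replace(g=GTensor(2.056, 1.909, 1.858))
        gr = global_fit(data, [init], g_bounds=0.02, multistart=2, seed=0)
        assert np.abs(gr.species[0].g.values - truth.g.values).max() < 1e-3

    def test_per_condition_weights_recovered(self, axial_species, rhombic_species,
                                             q_band):
        inst = q_band.replace(n_points=512)
        weight_sets = [(0.5, 0.5), (0.9, 0.1)]
        data = []
        for i, w in enumerate(weight_sets):
            spec, _ = generate_spectrum([axial_species, rhombic_species], w, inst,
                                        NoiseModel(snr=50.0, seed=100 + i),
                                        n_theta=16, n_phi=16)
            data.append(spec)
        gr = global_fit(data, [axial_species, rhombic_species], g_bounds=0.004,
                        multistart=1, n_theta=16, n_phi=16)
        for mix, w_true in zip(gr.mixtures, weight_sets):
            np.testing.assert_allclose(mix.normalized_weights, w_true, atol=0.03)

    def test_single_spectrum_degenerates_to_plain_fit(self, axial_species, q_band):
        target = simulate_mixture([axial_species], [1.0], q_band)
        gr = global_fit([target], [axial_species], g_bounds=0.002, multistart=1)
        fr = fit_weights(target, [axial_species])
        np.testing.assert_allclose(gr.mixtures[0].weights, fr.mixture.weights,
                                   rtol=1e-4)


class TestModelSelection:
    def test_residual_drops_then_plateaus(self, presets, q_band):
        a, r = presets["axial-A"], presets["rhombic-R"]
        spec, _ = generate_spectrum([a, r], [0.5, 0.5], q_band,
                                    NoiseModel(snr=100.0, seed=5))
        candidates = [a, r, presets["Q-band FID"], presets["Q-band ESE"]]
        table = model_selection(spec, candidates)
        res = table["residual_norm"].to_numpy()
        assert np.all(np.diff(res) <= 1e-12)  # nested models
        drop_12 = res[0] - res[1]
        drop_23 = res[1] - res[2]
        assert drop_12 > 10 * max(drop_23, 1e-12)

    def test_single_species_residual_at_noise_floor(self, axial_species, q_band):
        spec, _ = generate_spectrum([axial_species], [1.0], q_band,
                                    NoiseModel(snr=50.0, seed=9))
        table = model_selection(spec, [axial_species])
        pp = spec.intensity.max() - spec.intensity.min()
        expected = (pp / 50.0) * np.sqrt(spec.intensity.size)
        assert table["residual_norm"].iloc[0] == pytest.approx(expected, rel=0.15)

    def test_invalid_k(self, axial_species, q_band):
        target = simulate_mixture([axial_species], [1.0], q_band)
        with pytest.raises(ValueError):
            model_selection(target, [])
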