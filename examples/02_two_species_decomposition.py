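"""Decompose a noisy two-species spectrum into axial and rhombic weights.

Generates a synthetic Q-band (34 GHz) pseudo-modulated spectrum with a
1:2 axial:rhombic composition at SNR 20 — the composition reported for the
reduced enzyme at pH 6-7 — and recovers the weights by non-negative least
squares.
"""

from fesepr import NoiseModel, fit_weights, generate_spectrum, instrument_presets, preset_library

lib = preset_library()
species = [lib["axial-A"], lib["rhombic-R"]]
inst = instrument_presets()["q_band"]

spec, truth = generate_spectrum(species, [1.0, 2.0], inst,
                                NoiseModel(snr=20.0, seed=42))
fit = fit_weights(spec, species)

w = fit.mixture.weights
frac = fit.mixture.normalized_weights
print(f"true composition      : axial 0.333, rhombic 0.667 (1:2)")
print(f"recovered fractions   : axial {frac[0]:.3f}, rhombic {frac[1]:.3f}")
print(f"rhombic:axial ratio   : {w[1] / w[0]:.2f}  (generator used 2.0)")
print(f"residual norm         : {fit.residual_norm:.4f}")
print("The fractions are effective signal amplitudes, not spin counts:")
print("relaxation differences between species preclude absolute quantitation.")
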