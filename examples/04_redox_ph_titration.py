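"""Recover a midpoint potential and a pKa from synthetic titration series.

Runs the full pipeline for a potentiometric series: generate spectra whose
axial/rhombic balance follows a Nernst curve, decompose each spectrum,
then fit the recovered fractions.  The pH branch fits a Hill model to a
fraction-vs-pH series directly.
"""

import numpy as np

from fesepr import (
    ConditionSeries,
    NoiseModel,
    PhModel,
    TitrationModel,
    fit_midpoint,
    fit_pka,
    fit_weights,
    generate_condition_series,
    instrument_presets,
    ph_fraction,
    preset_library,
)

lib = preset_library()
pair = (lib["axial-A"], lib["rhombic-R"])
inst = instrument_presets()["q_band"].replace(n_points=512)

# --- potential series: spectra -> weights -> Nernst fit -------------------
e_true = -450.0
potentials = np.linspace(-570, -330, 7)
spectra, truth = generate_condition_series(
    pair, potentials, TitrationModel(E_m=e_true), inst,
    NoiseModel(snr=20.0, seed=11), n_theta=16, n_phi=16)
fractions = [fit_weights(row[0], list(pair), n_theta=16, n_phi=16)
             .mixture.normalized_weights[1] for row in spectra]
fit_e = fit_midpoint(ConditionSeries(potentials, fractions))
print(f"planted E_m = {e_true:.0f} mV vs SHE; "
      f"recovered {fit_e.model.E_m:.1f} +/- {fit_e.stderr.get('E_m', float('nan')):.1f} mV")
print("(the reduced, EPR-visible fraction grows toward negative potentials)")

# --- pH series: Hill fit on fractions -------------------------------------
pka_true = 6.8
ph = np.array([6.0, 6.5, 7.0, 7.5, 8.0, 9.0])
rng = np.random.default_rng(3)
f = np.clip(ph_fraction(ph, PhModel(pKa=pka_true)) + rng.normal(0, 0.03, ph.size), 0, 1)
fit_p = fit_pka(ConditionSeries(ph, f))
print(f"planted pKa = {pka_true}; recovered {fit_p.model.pKa:.2f} "
      f"+/- {fit_p.stderr.get('pKa', float('nan')):.2f}")
print("At pH 6.5 the protonation-linked (rhombic-like) fraction is ~2/3;")
print("by pH 9 it has vanished — the pattern seen in the pH-dependent spectra.")
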