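# Methods

## Spin model and scope

All simulations use a first-order S = 1/2 spin Hamiltonian with g-anisotropy
only.  Hyperfine structure, zero-field interactions, S > 1/2 manifolds,
exchange-coupled dimers and relaxation physics are deliberately out of
scope: for protein-bound [4Fe4S]¹⁺ clusters the field-swept lineshape at
X/Q band is set by the g-tensor and inhomogeneous broadening, and those are
the only quantities the analysis fits.  Temperature is carried as a
condition label with free per-condition weights, never as physics.

The resonance condition is B = hν/(g_eff μ_B) with
g_eff²(θ, φ) = g₁²l₁² + g₂²l₂² + g₃²l₃².  Principal values are stored in
descending order (g₁ ≥ g₂ ≥ g₃).  Constants are CODATA via
`scipy.constants`, exposed through a single frozen `PhysicalConstants`
object.

## Powder averaging

Orientations are integrated over one octant (sufficient by g-tensor
symmetry) on a deterministic equal-area product grid in (cos θ, φ): every
knot carries the same solid angle, so results are exactly reproducible —
a deliberate choice over Monte-Carlo orientation sampling.  The default is
32 × 32 = 1024 knots, user-tunable.

Each orientation contributes a broadened line at its resonance field with
the Aasa–Vänngård 1/g intensity factor for field-swept detection.  (The
orientation dependence of the transition moment is neglected; for the
g-anisotropies involved here, ≲ 10 %, it rescales intensities by ≲ 2 % and
does not move turning points.)  To keep coarse grids smooth, the analytic
spread of the resonance field across each grid cell — from the gradients of
g_eff in (cos θ, φ) — is folded into the Gaussian width as a uniform-cell
variance (Δx²/12 per dimension).  This variance-matching term vanishes as
the grid refines; with it, doubling the default grid changes the spectrum
by < 10⁻³ of its maximum, and the integral is stable to < 0.1 % under
doubling of either the grid or the field resolution.  Absorption integrals
are normalized to 1 so mixture weights act as relative amplitudes.

## Broadening model

Two terms combine per orientation:

- **g-strain**: independent Gaussian distributions on the principal
  g-values with widths σ_g = (σ₁, σ₂, σ₃), propagated to first order,
  σ_g,eff² = Σᵢ (gᵢ lᵢ²/g_eff)² σᵢ², and converted to a field width
  σ_B = B σ_g,eff/g_eff.  This width scales linearly with microwave
  frequency — the defining signature of g-strain.
- **residual linewidth** (mT): frequency-independent; Gaussian σ for the
  `gaussian` lineshape, Lorentzian HWHM for `lorentzian`/`voigt` (the voigt
  profile combines the Gaussian strain part with the Lorentzian residual).

The strain model is principal-axis Gaussian strain without cross
correlations — the standard minimal parameterization when the experiment
resolves only linewidths, not strain-correlation signatures.

## Pseudo-modulation

Echo-detected spectra are absorption-shaped; derivative-like presentation
uses the Fourier–Bessel first harmonic,
S₁ = irfft(2i·J₁(2π f a)·rfft(S)) with f in cycles/mT and a the modulation
amplitude in mT, the accepted numerical emulation of sinusoidal
field-modulation detection.  The kernel normalization is chosen so the
small-amplitude limit is exactly a·dS/dB (verified to < 10⁻³ relative at
a = linewidth/100).  Records shorter than 8 points fall back to a
central-difference derivative scaled by a.  Default amplitudes mirror the
study conditions: 1.4 mT at 9.7 GHz, 4 mT at 34 GHz.

## Decomposition and refinement

The linear step solves min‖Aw + Pb − y‖ with w ≥ 0 (species) and b free
(polynomial baseline, order ≤ 3, Legendre-scaled axis), via
`scipy.optimize.lsq_linear`.  Weights are reported both raw and normalized;
they are effective amplitudes, not spin counts.  Rank-deficient species
designs (condition number > 10¹⁰) are flagged with a `CollinearityWarning`
and the smallest-norm non-negative solution is reported — never silently
resolved.  Masks exclude field ranges (e.g. the g ≈ 2 radical region); the
paired baseline option handles smooth contamination instead.

Nonlinear refinement uses variable projection: the bounded trust-region
optimizer (`least_squares`, method `trf`) moves only g-values (and
optionally linewidths); weights are re-solved by the inner NNLS at every
residual evaluation.  This exploits the separable structure and guarantees
physical weights at all times.  Five jittered restarts (deterministic from
a seed) guard against local minima on broad rhombic features; solutions
within 10⁻⁸ of a bound are flagged `at_boundary`, and non-convergence is
flagged, never silent.  Parameter uncertainties come from the Gauss–Newton
covariance at the optimum.

Global fits share one species parameter set across spectra while weights
stay free per spectrum; each spectrum is simulated on its own instrument
settings and the model is never resampled onto a foreign field axis.
`model_selection` tabulates residual norm, AIC and BIC for nested 1..K
species models and deliberately selects nothing: with strongly overlapping
powder patterns the species count is not sharply identifiable, and the
table is a diagnostic only.

## Condition models

Redox: f(E) = 1/(1 + exp((E − E_m)·n_e·F/(RT))), potentials in mV vs SHE
with reduction favored at negative E; n_e defaults to 1 (the one-electron
2+/1+ couple) and the fit report always records whether it was fixed or
floated.  pH: f(pH) = f_high + (f_low − f_high)/(1 + 10^{n_H(pH − pKa)}),
running from f_low at acidic pH to f_high at basic pH.  The free plateaus
exist because real series show mixtures, not pure species, at the pH
extremes; the model is agnostic about whether the transition is a simple
protonation or proton-coupled electron transfer — both parameterize the
same sigmoid.  Estimators are weighted least squares with covariance-based
uncertainties.  Series lying entirely on one plateau (all fractions > 0.95
or < 0.05) or with fewer points than parameters are flagged
non-identifiable rather than returning a spurious midpoint.

## Valence isomers

Enumeration is combinatorial: choosing the mixed-valence pair among
C(4,2) = 6 site pairs fixes the ferrous pair, giving exactly six
assignments in lexicographic order.  Classification from a four-site
spin-population record requires the strict 2-positive/2-negative sign
pattern of an antiferromagnetic broken-symmetry state; the two most
positive sites form the mixed-valence pair and the margin is the population
gap between the groups.  Because the boundary always separates opposite
signs, the margin is strictly positive for any valid record and the
`TieError` path is purely defensive.  A large |Σρᵢ| triggers a warning
(threshold configurable, default 2 unpaired-electron units) rather than an
error, since population sums vary by scheme.  Pair-to-plane labels are
supplied via topology configuration, not hard-coded.  The module never maps
isomer assignments onto EPR species: that link is not established by any
computation this package performs.

## Synthetic data

The generator emulates echo-detected field sweeps: mixture powder spectrum
in the requested detection mode, plus (optionally) white Gaussian noise,
a polynomial baseline, and a narrow isotropic radical line near g = 2.004
scaled relative to the cluster signal's peak-to-peak amplitude.  SNR is
defined on the peak-to-peak of the noiseless detected signal, the usual
convention for derivative-like EPR traces; realized noise σ matches the
nominal value within 5 % for ≥ 1024 points.  Everything is bit-reproducible
from (parameters, seed); condition series spawn per-spectrum seeds
deterministically from one master seed and serialize their ground truth
alongside the spectra.

What the generator does **not** emulate: temperature-dependent relaxation
(per-temperature weights are free inputs), field-dependent noise,
instrument response and phase distortions, microwave-power saturation, and
the exchange-coupled radical features seen at low pH.  Passing tests
therefore demonstrate correctness of the inference machinery under the
stated statistical model, not robustness to every artifact of real
spectrometer data.

Species presets ship the four literature g-sets for the reduced cluster
labelled by method (X-band cw: 2.040/1.910/1.910; Q-band FID:
2.045/1.926/1.896; Q-band ESE: 2.050/1.915/1.852; a second Q-band ESE set:
2.054/1.921/1.848), plus editable `axial-A`/`rhombic-R` templates that
reuse the axial cw and rhombic 2014-style sets respectively — the two
species' refit values are not published as reusable numbers, so the
templates are literature-derived stand-ins.  Template strain (0.010 per
axis) and residual width (1.0 mT) are illustrative values typical of
protein-bound FeS clusters, chosen once; at Q band they produce the ~5 mT
feature widths seen in such spectra.

## Numerical choices and problem sizes

- Default field axes: 1024 points over 300–405 mT (9.7 GHz) or
  1120–1390 mT (34 GHz), covering all preset resonances with margin;
  windows that clip a species' resonances warn, windows excluding them all
  raise.
- Axiality tolerance 0.005: half the smallest g-difference resolved among
  the shipped literature sets.
- Field axes must be uniform to 10⁻⁹ of the axis scale, which a 12
  significant-digit ASCII round trip preserves.
- Monte-Carlo test sizes (50–100 noise realizations for weight/parameter
  recovery, 20 for full nonlinear g-refits, 10⁴ records for the
  classification oracle) were chosen as the smallest ensembles whose means
  are stable to well inside the asserted tolerances; recovery tests that
  refit spectra in a loop use reduced grids (16 × 16, 512 points), which
  the convergence results above show to be within a few × 10⁻³ of the
  converged spectrum.

## Known limitations

- No transition-probability anisotropy; intensities across very large
  g-anisotropy would need it.
- Lorentzian residual width plus g-strain uses a Voigt profile per
  orientation but no Lorentzian strain correlations.
- `fit_midpoint` treats n_e as continuous during optimization and rounds on
  report; strongly non-integer apparent n_e indicates an inadequate
  one-couple model rather than fractional electrons.
- The BES3T reader covers 1-D field sweeps (real data, XMIN/XWID/XPTS
  axes); 2-D experiments and companion gradient files are out of scope.
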