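"""Multi-species spectral decomposition.

A measured (or synthetic) field-swept spectrum is modelled as a non-negative
linear combination of per-species powder spectra, optionally plus a low-order
polynomial baseline:

    y(B) = sum_i w_i s_i(B; g_i, strain_i, lw_i) + p(B),   w_i >= 0

The weights are solved by non-negative least squares (baseline coefficients
unconstrained).  Nonlinear refinement of species parameters uses variable
projection: the outer bounded trust-region optimizer moves g-values (and
optionally linewidths) while the inner linear step re-solves the weights at
every iteration.  Global fits share one species parameter set across spectra
recorded at different frequencies or conditions, with free per-spectrum
weights — the computational counterpart of requiring frequency-invariant
g-values for a genuine species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .spin_sim import (
    GTensor,
    InstrumentConfig,
    SpeciesModel,
    Spectrum,
    apply_detection,
    powder_spectrum,
)

__all__ = [
    "MixtureState",
    "FitResult",
    "GlobalFitResult",
    "simulate_mixture",
    "fit_weights",
    "refine_species",
    "global_fit",
    "model_selection",
    "CollinearityWarning",
]

FieldRange = tuple[float, float]


class CollinearityWarning(UserWarning):
    """Raised when the species design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class MixtureState:
    """Species weights under one experimental condition."""

    species_refs: tuple[str, ...]
    weights: np.ndarray  # raw amplitudes, >= 0
    condition: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != len(self.species_refs):
            raise ValueError("one weight per species required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "species_refs", tuple(self.species_refs))

    @property
    def normalized_weights(self) -> np.ndarray:
        tot = self.weights.sum()
        return self.weights / tot if tot > 0 else self.weights.copy()


@dataclass
class FitResult:
    """Outcome of a single-spectrum decomposition or refinement."""

    mixture: MixtureState
    residual_norm: float
    baseline_coeffs: np.ndarray
    refined_species: list[SpeciesModel] | None = None
    uncertainties: dict[str, float] = field(default_factory=dict)
    mask: tuple[FieldRange, ...] = ()
    collinear: bool = False
    converged: bool = True
    at_boundary: bool = False
    n_iterations: int = 0
    model: np.ndarray | None = None  # best-fit trace on the target axis

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


@dataclass
class GlobalFitResult:
    """Shared-species fit across several spectra."""

    species: list[SpeciesModel]
    mixtures: list[MixtureState]
    residual_norms: list[float]
    pooled_residual_norm: float
    uncertainties: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# forward model


def simulate_mixture(
    species: Sequence[SpeciesModel],
    weights: Sequence[float],
    instrument: InstrumentConfig,
    n_theta: int = 32,
    n_phi: int = 32,
) -> Spectrum:
    """Weighted sum of per-species powder spectra in the instrument's mode."""
    if len(species) != len(weights):
        raise ValueError("need exactly one weight per species")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    absorption = instrument.replace(detection_mode="absorption")
    total = np.zeros(instrument.n_points)
    for sp, wi in zip(species, w):
        total += wi * powder_spectrum(sp, absorption, n_theta, n_phi).intensity
    spec = Spectrum(
        instrument.field_axis, total, instrument,
        {"origin": "simulated",
         "species": [sp.name for sp in species],
         "weights": w.tolist()},
    )
    return apply_detection(spec)


# ---------------------------------------------------------------------------
# linear step


def _mask_indices(field_axis: np.ndarray, mask: Sequence[FieldRange]) -> np.ndarray:
    keep = np.ones(field_axis.size, dtype=bool)
    for lo, hi in mask:
        keep &= ~((field_axis >= min(lo, hi)) & (field_axis <= max(lo, hi)))
    return keep

def _baseline_columns(field_axis: np.ndarray, order: int | None) -> np.ndarray:
    if order is None:
        return np.empty((field_axis.size, 0))
    if not 0 <= order <= 3:
        raise ValueError("baseline_order must be in 0..3 (or None for no baseline)")
    # scaled to [-1, 1] for conditioning
    x = 2 * (field_axis - field_axis[0]) / (field_axis[-1] - field_axis[0]) - 1
    return np.vander(x, order + 1, increasing=True)


def _species_design(
    species: Sequence[SpeciesModel],
    instrument: InstrumentConfig,
    n_theta: int,
    n_phi: int,
) -> np.ndarray:
    cols = []
    absorption = instrument.replace(detection_mode="absorption")
    for sp in species:
        s = powder_spectrum(sp, absorption, n_theta, n_phi)
        cols.append(apply_detection(Spectrum(s.field_axis, s.intensity, instrument,
                                             s.provenance)).intensity)
    return np.column_stack(cols)


def _solve_linear(
    design_species: np.ndarray,
    design_base: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """NNLS on species columns, free baseline. Returns (w, b, residual, collinear)."""
    n_sp = design_species.shape[1]
    n_b = design_base.shape[1]
    a = np.hstack([design_species, design_base])
    sv = np.linalg.svd(design_species, compute_uv=False) if n_sp else np.array([1.0])
    collinear = bool(sv[0] > 0 and sv[-1] / sv[0] < 1e-10)
    lb = np.concatenate([np.zeros(n_sp), np.full(n_b, -np.inf)])
    ub = np.full(n_sp + n_b, np.inf)
    res = optimize.lsq_linear(a, y, bounds=(lb, ub), method="bvls" if a.shape[1] <= 20 else "trf")
    coef = res.x
    if collinear:
        warnings.warn(
            "species spectra are collinear; reporting the smallest-norm "
            "non-negative solution", CollinearityWarning, stacklevel=3,
        )
    w = np.clip(coef[:n_sp], 0.0, None)
    b = coef[n_sp:]
    residual = a @ coef - y
    return w, b, residual, collinear


def fit_weights(
    target: Spectrum,
    species: Sequence[SpeciesModel],
    baseline_order: int | None = None,
    mask: Sequence[FieldRange] = (),
    n_theta: int = 32,
    n_phi: int = 32,
) -> FitResult:
    """Non-negative least-squares weights of known species in a spectrum.

    Species spectra are simulated on the target's instrument settings
    (frequency, window, detection mode).  ``mask`` excludes field ranges in
    mT — e.g. a narrow organic-radical region near g ~ 2 — from the fit.
    Weights are reported raw (amplitudes) in ``mixture.weights`` and as
    fractions via ``mixture.normalized_weights``.
    """
    if not species:
        raise ValueError("need at least one species")
    keep = _mask_indices(target.field_axis, mask)
    if not keep.any():
        raise ValueError("mask excludes the entire spectrum")
    a_sp = _species_design(species, target.instrument, n_theta, n_phi)
    a_b = _baseline_columns(target.field_axis, baseline_order)
    w, b, _, collinear = _solve_linear(a_sp[keep], a_b[keep], target.intensity[keep])
    model = a_sp @ w + (a_b @ b if b.size else 0.0)
    residual = (model - target.intensity)[keep]
    rnorm = float(np.linalg.norm(residual))

    # linear-model covariance on the unmasked points (active-set approximation)
    unc: dict[str, float] = {}
    a_full = np.hstack([a_sp, a_b])[keep]
    dof = max(keep.sum() - a_full.shape[1], 1)
    s2 = rnorm**2 / dof
    try:
        cov = s2 * np.linalg.pinv(a_full.T @ a_full)
        for i, sp in enumerate(species):
            unc[f"w[{sp.name}]"] = float(np.sqrt(max(cov[i, i], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        pass

    mixture = MixtureState(tuple(sp.name for sp in species), w,
                           dict(target.instrument.condition))
    return FitResult(mixture=mixture, residual_norm=rnorm, baseline_coeffs=b,
                     uncertainties=unc, mask=tuple(mask), collinear=collinear,
                     model=model)


# ---------------------------------------------------------------------------
# nonlinear refinement (variable projection)


def _pack_bounds(
    init: Sequence[SpeciesModel],
    g_bounds: float | Mapping[str, tuple[float, float]],
    vary_linewidth: bool,
    lw_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Flatten species parameters into (x0, lb, ub, names)."""
    x0, lb, ub, names = [], [], [], []
    for sp in init:
        for ax, gval in zip(("g1", "g2", "g3"), sp.g.values):
            pname = f"{sp.name}.{ax}"
            if isinstance(g_bounds, Mapping):
                if pname not in g_bounds:
                    raise ValueError(f"bounds missing for free parameter {pname}")
                lo, hi = g_bounds[pname]
            else:
                lo, hi = gval - g_bounds, gval + g_bounds
            if not lo <= gval <= hi:
                raise ValueError(f"initial {pname}={gval} outside bounds ({lo}, {hi})")
            x0.append(gval); lb.append(lo); ub.append(hi); names.append(pname)
        if vary_linewidth:
            pname = f"{sp.name}.lw"
            lo, hi = lw_bounds
            if not lo <= sp.residual_linewidth <= hi:
                raise ValueError(f"initial {pname} outside bounds")
            x0.append(sp.residual_linewidth); lb.append(lo); ub.append(hi)
            names.append(pname)
    return np.array(x0), np.array(lb), np.array(ub), names


def _unpack_species(
    x: np.ndarray, init: Sequence[SpeciesModel], vary_linewidth: bool
) -> list[SpeciesModel]:
    out, i = [], 0
    for sp in init:
        g = GTensor(*x[i:i + 3]); i += 3
        lw = sp.residual_linewidth
        if vary_linewidth:
            lw = float(x[i]); i += 1
        out.append(sp.replace(g=g, residual_linewidth=lw))
    return out


def refine_species(
    target: Spectrum,
    init: Sequence[SpeciesModel],
    g_bounds: float | Mapping[str, tuple[float, float]] = 0.03,
    vary_linewidth: bool = False,
    lw_bounds: tuple[float, float] = (0.05, 10.0),
    baseline_order: int | None = None,
    mask: Sequence[FieldRange] = (),
    multistart: int = 5,
    seed: int = 0,
    n_theta: int = 32,
    n_phi: int = 32,
    max_nfev: int | None = None,
) -> FitResult:
    """Bounded refinement of g-values (and optionally linewidths).

    Variable projection: at every trial parameter vector the weights (and
    baseline) are re-solved by the inner non-negative linear step, so the
    outer optimizer only sees the nonlinear shape parameters.  ``g_bounds``
    is either a half-width applied around each initial g-value or an
    explicit ``{"name.g1": (lo, hi), ...}`` map covering every free
    parameter.  ``multistart`` jittered restarts (deterministic from
    ``seed``) guard against local minima on broad rhombic features.
    """
    keep = _mask_indices(target.field_axis, mask)
    if not keep.any():
        raise ValueError("mask excludes the entire spectrum")
    x0, lb, ub, names = _pack_bounds(init, g_bounds, vary_linewidth, lw_bounds)
    a_b = _baseline_columns(target.field_axis, baseline_order)[keep]
    y = target.intensity[keep]

    def residuals(x: np.ndarray) -> np.ndarray:
        models = _unpack_species(x, init, vary_linewidth)
        a_sp = _species_design(models, target.instrument, n_theta, n_phi)[keep]
        _, _, r, _ = _solve_linear(a_sp, a_b, y)
        return r

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(multistart - 1, 0)):
        jitter = rng.uniform(-0.25, 0.25, size=x0.size) * (ub - lb)
        starts.append(np.clip(x0 + jitter, lb, ub))

    best = None
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            res = optimize.least_squares(
                residuals, s, bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10, max_nfev=max_nfev,
            )
        if best is None or res.cost < best.cost:
            best = res

    x_fit = best.x
    refined = _unpack_species(x_fit, init, vary_linewidth)
    a_sp = _species_design(refined, target.instrument, n_theta, n_phi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CollinearityWarning)
        w, b, _, collinear = _solve_linear(
            a_sp[keep], _baseline_columns(target.field_axis, baseline_order)[keep], y)
    model = a_sp @ w + (_baseline_columns(target.field_axis, baseline_order) @ b
                        if b.size else 0.0)
    rnorm = float(np.linalg.norm((model - target.intensity)[keep]))

    # parameter uncertainties from the Gauss-Newton covariance at the optimum
    unc: dict[str, float] = {}
    jac = best.jac
    dof = max(y.size - x_fit.size - len(init), 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        unc = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    span = ub - lb
    at_boundary = bool(np.any((x_fit - lb < 1e-8 * span) | (ub - x_fit < 1e-8 * span)))
    converged = best.status > 0
    if not converged:
        warnings.warn("refine_species did not converge within max_nfev", stacklevel=2)

    mixture = MixtureState(tuple(sp.name for sp in refined), w,
                           dict(target.instrument.condition))
    return FitResult(mixture=mixture, residual_norm=rnorm, baseline_coeffs=b,
                     refined_species=refined, uncertainties=unc, mask=tuple(mask),
                     collinear=collinear, converged=converged,
                     at_boundary=at_boundary, n_iterations=int(best.nfev),
                     model=model)


# ---------------------------------------------------------------------------
# global (multi-spectrum) fit


def global_fit(
    dataset: Sequence[Spectrum],
    init: Sequence[SpeciesModel],
    g_bounds: float | Mapping[str, tuple[float, float]] = 0.03,
    vary_linewidth: bool = False,
    lw_bounds: tuple[float, float] = (0.05, 10.0),
    baseline_order: int | None = None,
    multistart: int = 3,
    seed: int = 0,
    n_theta: int = 32,
    n_phi: int = 32,
) -> GlobalFitResult:
    """Joint fit of shared species parameters across several spectra.

    One species parameter set is optimized against all spectra at once;
    weights are re-solved per spectrum, so each condition or frequency keeps
    its own composition.  Each spectrum is simulated on its own instrument
    settings — the model is never resampled onto a foreign field axis.
    """
    if len(dataset) < 1:
        raise ValueError("dataset must contain at least one spectrum")
    x0, lb, ub, names = _pack_bounds(init, g_bounds, vary_linewidth, lw_bounds)
    baselines = [_baseline_columns(s.field_axis, baseline_order) for s in dataset]

    def residuals(x: np.ndarray) -> np.ndarray:
        models = _unpack_species(x, init, vary_linewidth)
        parts = []
        for spec, a_b in zip(dataset, baselines):
            a_sp = _species_design(models, spec.instrument, n_theta, n_phi)
            _, _, r, _ = _solve_linear(a_sp, a_b, spec.intensity)
            parts.append(r)
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(multistart - 1, 0)):
        jitter = rng.uniform(-0.25, 0.25, size=x0.size) * (ub - lb)
        starts.append(np.clip(x0 + jitter, lb, ub))

    best = None
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            res = optimize.least_squares(residuals, s, bounds=(lb, ub),
                                         method="trf", xtol=1e-10, ftol=1e-10)
        if best is None or res.cost < best.cost:
            best = res

    refined = _unpack_species(best.x, init, vary_linewidth)
    mixtures, rnorms = [], []
    for spec, a_b in zip(dataset, baselines):
        a_sp = _species_design(refined, spec.instrument, n_theta, n_phi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            w, _, r, _ = _solve_linear(a_sp, a_b, spec.intensity)
        mixtures.append(MixtureState(tuple(sp.name for sp in refined), w,
                                     dict(spec.instrument.condition)))
        rnorms.append(float(np.linalg.norm(r)))

    unc: dict[str, float] = {}
    n_obs = sum(s.intensity.size for s in dataset)
    dof = max(n_obs - best.x.size - len(init) * len(dataset), 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
        unc = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    span = ub - lb
    at_boundary = bool(np.any((best.x - lb < 1e-8 * span) | (ub - best.x < 1e-8 * span)))
    return GlobalFitResult(
        species=refined, mixtures=mixtures, residual_norms=rnorms,
        pooled_residual_norm=float(np.sqrt(sum(r**2 for r in rnorms))),
        uncertainties=unc, converged=best.status > 0, at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# model selection


def model_selection(
    target: Spectrum,
    candidates: Sequence[SpeciesModel],
    k_max: int | None = None,
    baseline_order: int | None = None,
    mask: Sequence[FieldRange] = (),
    n_theta: int = 32,
    n_phi: int = 32,
) -> pd.DataFrame:
    """Residual and parsimony criteria for nested 1..K species models.

    Fits the first k candidates for each k and tabulates the residual norm,
    AIC and BIC.  The residual is monotone non-increasing in k because the
    models are nested.  No winner is selected: the table is a diagnostic,
    not a decision — with strongly overlapping powder patterns the species
    count is not sharply identifiable.
    """
    k_max = len(candidates) if k_max is None else k_max
    if k_max < 1:
        raise ValueError("need at least one candidate species")
    if k_max > len(candidates):
        raise ValueError("k_max exceeds the number of candidate species")
    keep = _mask_indices(target.field_axis, mask)
    n = int(keep.sum())
    rows = []
    for k in range(1, k_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            fr = fit_weights(target, candidates[:k], baseline_order, mask,
                             n_theta, n_phi)
        rss = fr.residual_norm**2
        p = k + (baseline_order + 1 if baseline_order is not None else 0)
        ll_term = n * np.log(max(rss, 1e-300) / n)
        rows.append({"k": k, "residual_norm": fr.residual_norm, "rss": rss,
                     "n_params": p, "aic": ll_term + 2 * p,
                     "bic": ll_term + p * np.log(n)})
    return pd.DataFrame(rows)
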