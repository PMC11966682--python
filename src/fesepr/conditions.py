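"""Condition models: redox (Nernst) and pH (Hill/Henderson-Hasselbalch) links.

Species fractions measured by spectral decomposition at a series of applied
potentials or pH values are connected to thermodynamic parameters through
two one-site models:

* Nernst: the EPR-visible reduced fraction of an n-electron couple,
  f(E) = 1 / (1 + exp((E - E_m) n F / (R T))), with E and the midpoint
  potential E_m in mV vs SHE.  Reduction is favored at more negative E.

* Protonation: the fraction of the protonation-linked (low-pH) form,
  f(pH) = f_high + (f_low - f_high) / (1 + 10^(n_H (pH - pKa))), with Hill
  coefficient n_H and free plateaus so that partial conversion at the pH
  extremes — a mixture rather than a pure species — is representable.

Estimators fit these curves to a weight-vs-condition series by weighted
least squares and report parameter uncertainties from the fit covariance.
Series lying entirely on one plateau carry no information about the
transition; such fits are flagged non-identifiable instead of returning a
spuriously precise midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .constants import CONST

__all__ = [
    "TitrationModel",
    "PhModel",
    "ConditionSeries",
    "nernst_fraction",
    "ph_fraction",
    "fit_midpoint",
    "fit_pka",
    "TitrationFit",
    "PhFit",
]


@dataclass(frozen=True)
class TitrationModel:
    """One-couple Nernst model: midpoint E_m (mV vs SHE), n_e electrons, T (K)."""

    E_m: float
    n_e: int = 1
    T: float = 298.15

    def __post_init__(self) -> None:
        if not (isinstance(self.n_e, (int, np.integer)) and self.n_e >= 1):
            raise ValueError("n_e must be an integer >= 1")
        if self.T <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in mV (25.693 mV at 298.15 K)."""
        return CONST.R * self.T / CONST.F * 1e3


@dataclass(frozen=True)
class PhModel:
    """Single-pKa Hill model with free plateaus.

    ``f_low``/``f_high`` are the limiting fractions of the
    protonation-linked species at the acidic/basic extremes; ``n_H`` is the
    Hill coefficient (cooperativity).
    """

    pKa: float
    n_H: float = 1.0
    f_low: float = 1.0
    f_high: float = 0.0

    def __post_init__(self) -> None:
        if self.n_H <= 0:
            raise ValueError("n_H must be > 0")
        for nm in ("f_low", "f_high"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionSeries:
    """Per-condition normalized weight of one species, with optional sigmas.

    ``condition`` is in mV vs SHE for potential series or pH units for pH
    series.  Points are sorted by condition on construction.
    """

    condition: np.ndarray
    weight: np.ndarray
    sigma: np.ndarray | None = None
    species: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.condition, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if c.ndim != 1 or c.size != w.size:
            raise ValueError("condition and weight must be 1-D of equal length")
        if np.any((w < -1e-9) | (w > 1 + 1e-9)):
            raise ValueError("weights must lie in [0, 1]")
        s = None if self.sigma is None else np.asarray(self.sigma, dtype=float)
        if s is not None and s.size != c.size:
            raise ValueError("sigma must match the series length")
        order = np.argsort(c)
        if np.any(np.diff(c[order]) == 0):
            raise ValueError("condition values must be distinct")
        object.__setattr__(self, "condition", c[order])
        object.__setattr__(self, "weight", np.clip(w[order], 0.0, 1.0))
        object.__setattr__(self, "sigma", None if s is None else s[order])

    def __len__(self) -> int:
        return self.condition.size


@dataclass
class TitrationFit:
    model: TitrationModel
    stderr: dict[str, float]
    residual_norm: float
    identifiable: bool
    wide_uncertainty: bool
    message: str = ""


@dataclass
class PhFit:
    model: PhModel
    stderr: dict[str, float]
    residual_norm: float
    identifiable: bool
    wide_uncertainty: bool
    message: str = ""


def nernst_fraction(E: float | np.ndarray, model: TitrationModel) -> float | np.ndarray:
    """Reduced (EPR-visible) fraction at applied potential E (mV vs SHE).

    Strictly decreasing in E; exactly 1/2 at E = E_m; tends to 1 as
    E -> -inf (fully reduced) and 0 as E -> +inf.
    """
    e = np.asarray(E, dtype=float)
    x = (e - model.E_m) * model.n_e / model.rt_over_f_mV
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return float(out) if np.isscalar(E) else out


def ph_fraction(pH: float | np.ndarray, model: PhModel) -> float | np.ndarray:
    """Fraction of the protonation-linked species at a given pH.

    Monotone in pH, running from f_low (acidic) to f_high (basic); midpoint
    (f_low + f_high)/2 at pH = pKa; n_H -> inf gives a step at the pKa.
    """
    p = np.asarray(pH, dtype=float)
    x = model.n_H * (p - model.pKa) * np.log(10.0)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.exp(x))
    out = model.f_high + (model.f_low - model.f_high) * frac
    return float(out) if np.isscalar(pH) else out


def _plateau_flags(w: np.ndarray, lo: float = 0.05, hi: float = 0.95) -> bool:
    """True when the series never crosses the transition region."""
    return bool(np.all(w > hi) or np.all(w < lo))


def fit_midpoint(
    series: ConditionSeries,
    n_e: int | None = 1,
    T: float = 298.15,
) -> TitrationFit:
    """Estimate the midpoint potential from a fraction-vs-potential series.

    ``n_e`` fixed (default 1, the one-electron [4Fe4S]2+/1+ couple — the fit
    report records that it was fixed by default) or ``None`` to float it.
    Fewer than 4 points, points all on one side of the transition, or an
    all-plateau series produce a wide-uncertainty / non-identifiable flag.
    """
    e, w = series.condition, series.weight
    sig = series.sigma if series.sigma is not None else np.ones_like(w)
    if _plateau_flags(w):
        mid = float(np.median(e))
        return TitrationFit(
            model=TitrationModel(E_m=mid, n_e=n_e or 1, T=T),
            stderr={}, residual_norm=0.0, identifiable=False,
            wide_uncertainty=True,
            message="series lies entirely on one plateau; E_m not identifiable",
        )
    sparse = len(series) < 4 or not (w.min() < 0.5 < w.max())

    fix_n = n_e is not None
    # initial E_m: condition closest to f = 0.5
    x0 = [float(e[np.argmin(np.abs(w - 0.5))])] + ([] if fix_n else [1.0])

    rtf = CONST.R * T / CONST.F * 1e3  # thermal voltage, mV

    def resid(x: np.ndarray) -> np.ndarray:
        # n_e treated as continuous during optimization, rounded on report
        ne = float(n_e) if fix_n else float(x[1])
        arg = (e - float(x[0])) * ne / rtf
        f = 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))
        return (f - w) / sig

    lb = [-np.inf] + ([] if fix_n else [0.25])
    ub = [np.inf] + ([] if fix_n else [4.0])
    res = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    em = float(res.x[0])
    ne_fit = n_e if fix_n else max(int(round(res.x[1])), 1)
    stderr: dict[str, float] = {}
    dof = max(len(series) - res.x.size, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        stderr["E_m"] = float(np.sqrt(max(cov[0, 0], 0.0)))
        if not fix_n:
            stderr["n_e"] = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    return TitrationFit(
        model=TitrationModel(E_m=em, n_e=ne_fit, T=T),
        stderr=stderr, residual_norm=float(np.sqrt(2 * res.cost)),
        identifiable=True, wide_uncertainty=sparse,
        message="n_e fixed at %s by default" % n_e if fix_n else "n_e floated",
    )


def fit_pka(
    series: ConditionSeries,
    n_H: float | None = 1.0,
    fit_plateaus: bool = False,
) -> PhFit:
    """Estimate the pKa (and optionally n_H and the plateaus) from a series."""
    p, w = series.condition, series.weight
    sig = series.sigma if series.sigma is not None else np.ones_like(w)
    if _plateau_flags(w):
        return PhFit(
            model=PhModel(pKa=float(np.median(p))), stderr={}, residual_norm=0.0,
            identifiable=False, wide_uncertainty=True,
            message="series lies entirely on one plateau; pKa not identifiable",
        )
    n_free = 1 + (n_H is None) + 2 * fit_plateaus
    if len(series) <= n_free + 1:
        return PhFit(
            model=PhModel(pKa=float(np.median(p))), stderr={}, residual_norm=0.0,
            identifiable=False, wide_uncertainty=True,
            message=f"{len(series)} points cannot constrain {n_free} parameters",
        )

    fix_n = n_H is not None
    x0 = [float(p[np.argmin(np.abs(w - 0.5 * (w.max() + w.min())))])]
    lb, ub = [p.min() - 5.0], [p.max() + 5.0]
    if not fix_n:
        x0 += [1.0]; lb += [0.1]; ub += [6.0]
    if fit_plateaus:
        x0 += [float(w.max()), float(w.min())]; lb += [0.0, 0.0]; ub += [1.0, 1.0]
    names = ["pKa"] + ([] if fix_n else ["n_H"]) + (["f_low", "f_high"] if fit_plateaus else [])

    def build(x: np.ndarray) -> PhModel:
        i = 1
        nh = float(n_H) if fix_n else float(x[1])
        if not fix_n:
            i = 2
        fl, fh = (float(x[i]), float(x[i + 1])) if fit_plateaus else (1.0, 0.0)
        return PhModel(pKa=float(x[0]), n_H=nh, f_low=fl, f_high=fh)

    def resid(x: np.ndarray) -> np.ndarray:
        return (ph_fraction(p, build(x)) - w) / sig

    res = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    stderr: dict[str, float] = {}
    dof = max(len(series) - res.x.size, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        stderr = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    return PhFit(model=build(res.x), stderr=stderr,
                 residual_norm=float(np.sqrt(2 * res.cost)),
                 identifiable=True, wide_uncertainty=len(series) < 4,
                 message="n_H fixed at %s by default" % n_H if fix_n else "n_H floated")
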