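"""Per-animal compartmental fitting and model selection.

Fitting is weighted nonlinear least squares on the closed-form model,
initialised by curve stripping (method of residuals).  Positivity is
enforced by optimising log-transformed parameters with a
Levenberg–Marquardt solver.  Goodness of fit uses the WinNonlin
convention

    AIC = n ln(WRSS) + 2p        SBC = n ln(WRSS) + p ln(n)

which omits the additive constants of the Gaussian likelihood; values
are comparable between models fitted to the same points and weights,
not across conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ModelSelectionError,
    StrippingError,
)
from .pk_model import (
    ConcentrationProfile,
    DoseRegimen,
    MacroParams,
    MicroParams,
    OneCompParams,
    clearance_from_micro,
    derived_params,
    macro_from_micro,
    micro_from_macro,
)

__all__ = [
    "WeightingScheme",
    "FitResult",
    "PopulationSummary",
    "strip_curve",
    "fit_compartmental",
    "aic",
    "sbc",
    "select_model",
    "summarize_population",
    "TABLE1_ROWS",
]

_WEIGHT_KINDS = ("uniform", "inverse_y", "inverse_y_squared")

#: Row order of the published population summary.
TABLE1_ROWS = (
    "Vc", "V2", "Vss", "CL", "CLD2",
    "T_half_alpha", "T_half_beta", "AUC", "MRT",
    "K10", "K12", "K21",
)


@dataclass(frozen=True)
class WeightingScheme:
    """Observation weights: uniform, 1/y or 1/y² (y = observed)."""

    kind: str = "uniform"

    def __post_init__(self):
        if self.kind not in _WEIGHT_KINDS:
            raise InvalidParameterError(
                f"weighting kind must be one of {_WEIGHT_KINDS}, got {self.kind!r}"
            )

    def weights(self, observed: np.ndarray) -> np.ndarray:
        if self.kind == "uniform":
            return np.ones_like(observed)
        if self.kind == "inverse_y":
            return 1.0 / observed
        return 1.0 / observed**2


@dataclass(frozen=True)
class FitResult:
    """Result of one animal × one model order."""

    params: MicroParams | OneCompParams
    n_obs: int
    n_params: int
    wrss: float
    aic: float
    sbc: float
    converged: bool
    n_iter: int
    subject_id: str = ""

    def __post_init__(self):
        if self.wrss < 0:
            raise InvalidParameterError("wrss must be >= 0")
        if self.n_params not in (2, 4):
            raise InvalidParameterError("n_params must be 2 (1-comp) or 4 (2-comp)")


@dataclass(frozen=True)
class PopulationSummary:
    """Arithmetic mean and standard error per parameter across animals.

    ``table`` is indexed by the 12 summary rows with columns
    ``mean`` and ``se`` (SE = SD/sqrt(n), sample SD).
    """

    table: pd.DataFrame
    n_animals: int


def _usable_points(profile: ConcentrationProfile, d: DoseRegimen):
    mask = profile.quantifiable_mask(exclude_predose_at=d.admin_time_h)
    return profile.times_h[mask], profile.concentrations[mask]


def strip_curve(
    profile: ConcentrationProfile,
    n_terminal: int = 4,
    d: DoseRegimen | None = None,
) -> MacroParams:
    """Method-of-residuals initial estimates for the bi-exponential.

    A log-linear regression on the last ``n_terminal`` quantifiable
    points yields (B, beta); the log of the positive residuals of the
    earlier points against that terminal line yields (A, alpha).  If the
    residuals do not support an alpha phase (mono-exponential data) the
    fallback assigns A from the time-zero surplus (possibly ~0) with
    alpha set an order of magnitude above beta.
    """
    d = d or DoseRegimen(dose_per_kg=500.0)
    t, c = _usable_points(profile, d)
    n = len(t)
    if n < 5:
        raise InsufficientDataError(f"curve stripping needs >= 5 quantifiable points, got {n}")
    if not (3 <= n_terminal < n):
        raise InvalidParameterError("require 3 <= n_terminal < number of points")

    tt, ct = t[-n_terminal:], c[-n_terminal:]
    res_t = stats.linregress(tt, np.log(ct))
    if res_t.slope >= 0:
        raise StrippingError("terminal phase does not decay; cannot strip")
    beta = -res_t.slope
    coef_b = math.exp(res_t.intercept)

    te, ce = t[:-n_terminal], c[:-n_terminal]
    resid = ce - coef_b * np.exp(-beta * te)
    pos = resid > 0
    if np.sum(pos) >= 2:
        res_a = stats.linregress(te[pos], np.log(resid[pos]))
        if res_a.slope < 0 and -res_a.slope > beta:
            return MacroParams(
                coef_a=math.exp(res_a.intercept),
                coef_b=coef_b,
                alpha=-res_a.slope,
                beta=beta,
            )
    # fallback: beta phase only; alpha phase from the surplus at the first point
    surplus = max(c[0] - coef_b * math.exp(-beta * t[0]), 0.0)
    return MacroParams(coef_a=surplus, coef_b=coef_b, alpha=10.0 * beta, beta=beta)


def _predict_2c(theta: np.ndarray, dose: float, t: np.ndarray) -> np.ndarray:
    vc, k10, k12, k21 = np.exp(theta)
    s = k10 + k12 + k21
    prod = k10 * k21
    sq = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + sq)
    beta = prod / alpha if alpha > 0 else 0.0
    c0 = dose / vc
    denom = alpha - beta
    if denom <= 0:  # degenerate point in parameter space; measure zero
        return np.full_like(t, c0 * math.exp(-alpha * np.mean(t)))
    a = c0 * (alpha - k21) / denom
    b = c0 * (k21 - beta) / denom
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


def _predict_1c(theta: np.ndarray, dose: float, t: np.ndarray) -> np.ndarray:
    v, k = np.exp(theta)
    return (dose / v) * np.exp(-k * t)


def _init_1c(t: np.ndarray, c: np.ndarray, dose: float) -> np.ndarray:
    res = stats.linregress(t, np.log(c))
    k = max(-res.slope, 1e-6)
    v = dose / math.exp(res.intercept)
    return np.log(np.array([v, k]))


def fit_compartmental(
    profile: ConcentrationProfile,
    d: DoseRegimen,
    n_compartments: int = 2,
    weighting: WeightingScheme = WeightingScheme("uniform"),
    init: MacroParams | None = None,
    max_iter: int = 500,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the 1- or 2-compartment
    IV-bolus model to one animal's quantifiable points.

    BLOQ samples and the pre-dose sample are excluded before fitting.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    if n_compartments not in (1, 2):
        raise InvalidParameterError("n_compartments must be 1 or 2")
    t, c = _usable_points(profile, d)
    n_params = 4 if n_compartments == 2 else 2
    if len(t) == 0:
        raise InsufficientDataError("no quantifiable points (all BLOQ or pre-dose)")
    if len(t) < n_params + 1:
        raise InsufficientDataError(
            f"{n_compartments}-compartment fit needs >= {n_params + 1} points, got {len(t)}"
        )
    # deterministic given identical inputs regardless of row order
    order = np.argsort(t)
    t, c = t[order], c[order]

    w = weighting.weights(c)
    sw = np.sqrt(w)
    dose = d.dose_per_kg

    if n_compartments == 2:
        if init is None:
            try:
                init = strip_curve(profile, n_terminal=min(4, len(t) - 1), d=d)
            except (StrippingError, InsufficientDataError, InvalidParameterError):
                init = None
        if init is not None:
            p0 = micro_from_macro(init, d)
            theta0 = np.log(np.array([p0.vc, p0.k10, max(p0.k12, 1e-6), p0.k21]))
        else:  # crude but scale-aware default
            res = stats.linregress(t[-3:], np.log(c[-3:]))
            beta = max(-res.slope, 1e-3)
            theta0 = np.log(np.array([dose / c[0], beta, 10 * beta, 10 * beta]))
        model = _predict_2c
    else:
        theta0 = _init_1c(t, c, dose)
        model = _predict_1c

    def residuals(theta):
        return sw * (c - model(theta, dose, t))

    # log-parameter bounds keep every rate/volume in (e^-25, e^25): wide
    # enough for any physiologic value, tight enough that exp never
    # under/overflows on pathological noisy replicates
    theta0 = np.clip(theta0, -24.0, 24.0)
    sol = optimize.least_squares(
        residuals,
        theta0,
        method="trf",
        bounds=(-25.0, 25.0),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * (n_params + 1),
    )
    wrss = float(np.sum(sol.fun**2))
    converged = bool(sol.status > 0)
    if n_compartments == 2:
        vc, k10, k12, k21 = np.exp(sol.x)
        params: MicroParams | OneCompParams = MicroParams(vc=vc, k10=k10, k12=k12, k21=k21)
    else:
        v, k = np.exp(sol.x)
        params = OneCompParams(v=v, k=k)
    fit = FitResult(
        params=params,
        n_obs=len(t),
        n_params=n_params,
        wrss=wrss,
        aic=math.nan,
        sbc=math.nan,
        converged=converged,
        n_iter=int(sol.nfev),
        subject_id=profile.subject_id,
    )
    return FitResult(
        params=fit.params,
        n_obs=fit.n_obs,
        n_params=fit.n_params,
        wrss=fit.wrss,
        aic=aic(fit),
        sbc=sbc(fit),
        converged=fit.converged,
        n_iter=fit.n_iter,
        subject_id=fit.subject_id,
    )


def aic(fit: FitResult) -> float:
    """n·ln(WRSS) + 2p; −inf sentinel for a perfect (WRSS = 0) fit."""
    if fit.wrss == 0.0:
        return -math.inf
    return fit.n_obs * math.log(fit.wrss) + 2.0 * fit.n_params


def sbc(fit: FitResult) -> float:
    """n·ln(WRSS) + p·ln(n); −inf sentinel for a perfect fit."""
    if fit.wrss == 0.0:
        return -math.inf
    return fit.n_obs * math.log(fit.wrss) + fit.n_params * math.log(fit.n_obs)


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Lowest-AIC converged fit; ties broken by fewer parameters, then SBC."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ModelSelectionError("no converged fits to select from")
    return min(converged, key=lambda f: (f.aic, f.n_params, f.sbc))


def _table1_values(p: MicroParams, d: DoseRegimen) -> dict[str, float]:
    cp = clearance_from_micro(p)
    dv = derived_params(p, d)
    return {
        "Vc": p.vc,
        "V2": cp.v2,
        "Vss": dv.vss,
        "CL": cp.cl,
        "CLD2": cp.cld2,
        "T_half_alpha": dv.t_half_alpha,
        "T_half_beta": dv.t_half_beta,
        "AUC": dv.auc_inf,
        "MRT": dv.mrt,
        "K10": p.k10,
        "K12": p.k12,
        "K21": p.k21,
    }


def summarize_population(fits: Sequence[FitResult], d: DoseRegimen) -> PopulationSummary:
    """Population summary in the published 12-row layout.

    Derived parameters are computed per animal first, then averaged;
    the mean of a derived quantity is therefore not in general equal to
    the quantity evaluated at the mean micro constants.  Defined for
    two-compartment fits only; mixed model orders raise.
    """
    if len(fits) < 2:
        raise InsufficientDataError("population summary needs >= 2 animals")
    orders = {f.n_params for f in fits}
    if len(orders) != 1:
        raise InvalidParameterError("all fits must share the same model order")
    if not all(isinstance(f.params, MicroParams) for f in fits):
        raise InvalidParameterError(
            "population summary is defined for the two-compartment model"
        )
    rows = [_table1_values(f.params, d) for f in fits]
    frame = pd.DataFrame(rows)[list(TABLE1_ROWS)]
    n = len(frame)
    table = pd.DataFrame(
        {"mean": frame.mean(axis=0), "se": frame.std(axis=0, ddof=1) / math.sqrt(n)}
    )
    return PopulationSummary(table=table, n_animals=n)
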