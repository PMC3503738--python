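"""One- and two-compartment intravenous-bolus disposition models.

The two-compartment model treats the body as a central compartment
(plasma plus rapidly equilibrating tissues, volume ``vc``) exchanging
drug with a peripheral compartment by first-order micro-rate constants:
``k10`` (elimination from central), ``k12`` (central to peripheral) and
``k21`` (peripheral to central).  After an IV bolus the plasma
concentration follows the bi-exponential

    C(t) = A exp(-alpha t) + B exp(-beta t)

where ``-alpha`` and ``-beta`` are the roots of
``s^2 + (k10 + k12 + k21) s + k10 k21 = 0`` and
``A = (D/vc)(alpha - k21)/(alpha - beta)``,
``B = (D/vc)(k21 - beta)/(alpha - beta)``.

Three equivalent parameterizations are provided.  :class:`MicroParams`
is the canonical internal form; :class:`ClearanceParams` (CL, CLD2, V2)
and :class:`MacroParams` (A, B, alpha, beta) are views converted at the
boundary.  Canonical units are hours, µg/mL, mL/kg and µg/kg: every
volume and clearance is normalised to bodyweight, so a 0.5 mg/kg label
dose enters as 500 µg/kg exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "DoseRegimen",
    "MicroParams",
    "ClearanceParams",
    "MacroParams",
    "DerivedParams",
    "OneCompParams",
    "ConcentrationProfile",
    "micro_from_clearance",
    "clearance_from_micro",
    "macro_from_micro",
    "micro_from_macro",
    "predict_concentration",
    "derived_params",
]

_LN2 = math.log(2.0)


def _require_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (np.isfinite(value) and value > 0):
            raise InvalidParameterError(
                f"{type(obj).__name__}.{name} must be finite and > 0, got {value!r}"
            )


@dataclass(frozen=True)
class DoseRegimen:
    """A single weight-normalised IV bolus.

    ``dose_per_kg`` is in µg/kg (the study's 0.5 mg/kg dose is 500).
    """

    dose_per_kg: float
    route: str = "IV bolus"
    admin_time_h: float = 0.0

    def __post_init__(self):
        _require_positive(self, "dose_per_kg")
        if self.admin_time_h < 0:
            raise InvalidParameterError("admin_time_h must be >= 0")


@dataclass(frozen=True)
class MicroParams:
    """Two-compartment micro-rate constants (canonical parameterization).

    ``k12 = 0`` is tolerated as the mono-exponential limit; all other
    fields must be strictly positive.
    """

    vc: float  # mL/kg
    k10: float  # 1/h
    k12: float  # 1/h
    k21: float  # 1/h

    def __post_init__(self):
        _require_positive(self, "vc", "k10", "k21")
        if not (np.isfinite(self.k12) and self.k12 >= 0):
            raise InvalidParameterError("k12 must be finite and >= 0")


@dataclass(frozen=True)
class ClearanceParams:
    """Clearance/volume view: CL, distributional clearance, peripheral volume."""

    vc: float  # mL/kg
    cl: float  # mL/h/kg
    cld2: float  # mL/h/kg
    v2: float  # mL/kg

    def __post_init__(self):
        _require_positive(self, "vc", "cl", "cld2", "v2")


@dataclass(frozen=True)
class MacroParams:
    """Bi-exponential macro constants: C(t) = A e^(-alpha t) + B e^(-beta t)."""

    coef_a: float  # µg/mL
    coef_b: float  # µg/mL
    alpha: float  # 1/h
    beta: float  # 1/h

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise InvalidParameterError("alpha/beta must be finite")
        if not self.alpha > self.beta > 0:
            raise InvalidParameterError(
                f"require alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.coef_a < 0 or self.coef_b < 0:
            raise InvalidParameterError("coefficients A and B must be >= 0")
        if self.coef_a + self.coef_b <= 0:
            raise InvalidParameterError("A + B must be > 0 (C(0) = dose/vc)")


@dataclass(frozen=True)
class DerivedParams:
    """Secondary parameters reported in population summaries."""

    vss: float  # mL/kg
    t_half_alpha: float  # h
    t_half_beta: float  # h
    auc_inf: float  # h·µg/mL
    mrt: float  # h
    cl: float  # mL/h/kg


@dataclass(frozen=True)
class OneCompParams:
    """One-compartment IV bolus: C(t) = (dose/v) e^(-k t)."""

    v: float  # mL/kg
    k: float  # 1/h

    def __post_init__(self):
        _require_positive(self, "v", "k")


@dataclass
class ConcentrationProfile:
    """One subject's analyte time course with LOQ metadata.

    ``bloq`` marks samples below the limit of quantification; if not
    supplied it is derived as ``concentrations < loq``.  Times must be
    strictly increasing and non-negative (hours).
    """

    subject_id: str
    treatment: str
    analyte: str
    times_h: np.ndarray
    concentrations: np.ndarray
    loq: float = 0.0
    bloq: np.ndarray | None = None

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.concentrations.shape:
            raise InvalidParameterError("times and concentrations must be equal-length 1-D")
        if len(self.times_h) and self.times_h[0] < 0:
            raise InvalidParameterError("times must be >= 0")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.loq < 0:
            raise InvalidParameterError("loq must be >= 0")
        if self.bloq is None:
            self.bloq = self.concentrations < self.loq
        else:
            self.bloq = np.asarray(self.bloq, dtype=bool)
            if self.bloq.shape != self.times_h.shape:
                raise InvalidParameterError("bloq mask must match times")

    def __len__(self) -> int:
        return len(self.times_h)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConcentrationProfile):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.treatment == other.treatment
            and self.analyte == other.analyte
            and self.loq == other.loq
            and np.array_equal(self.times_h, other.times_h)
            and np.array_equal(self.concentrations, other.concentrations)
            and np.array_equal(self.bloq, other.bloq)
        )

    def quantifiable_mask(self, exclude_predose_at: float | None = None) -> np.ndarray:
        """Boolean mask of usable points: above LOQ, optionally dropping
        the sample at the administration time (pre-dose for an IV bolus)."""
        mask = ~self.bloq
        if exclude_predose_at is not None:
            mask = mask & (self.times_h > exclude_predose_at)
        return mask

    @property
    def n_quantifiable(self) -> int:
        return int(np.sum(~self.bloq))


# ---------------------------------------------------------------------------
# parameter conversions


def micro_from_clearance(p: ClearanceParams) -> MicroParams:
    """Convert the clearance family to micro constants.

    k10 = CL/Vc, k12 = CLD2/Vc, k21 = CLD2/V2.
    """
    return MicroParams(vc=p.vc, k10=p.cl / p.vc, k12=p.cld2 / p.vc, k21=p.cld2 / p.v2)


def clearance_from_micro(p: MicroParams) -> ClearanceParams:
    """Inverse of :func:`micro_from_clearance`: CL = k10·Vc, CLD2 = k12·Vc,
    V2 = k12·Vc/k21.  Requires k12 > 0 (otherwise V2 would be zero)."""
    if p.k12 <= 0:
        raise InvalidParameterError("clearance view undefined for k12 == 0 (V2 = 0)")
    return ClearanceParams(vc=p.vc, cl=p.k10 * p.vc, cld2=p.k12 * p.vc, v2=p.k12 * p.vc / p.k21)


def macro_from_micro(p: MicroParams, d: DoseRegimen) -> MacroParams:
    """Hybrid (macro) constants of the bi-exponential solution.

    alpha and beta are the negated roots of
    ``s^2 + (k10+k12+k21) s + k10·k21``; Vieta's identities
    (alpha+beta = k10+k12+k21, alpha·beta = k10·k21) hold by
    construction, as does A + B = dose/vc.
    """
    s = p.k10 + p.k12 + p.k21
    prod = p.k10 * p.k21
    disc = s * s - 4.0 * prod
    if disc <= 0.0:
        # For distinct positive rate constants disc > 0 always; equality
        # requires k12 = 0 and k10 = k21 (repeated root).
        raise InvalidParameterError(
            "degenerate disposition (alpha == beta); repeated-root form unsupported"
        )
    sq = math.sqrt(disc)
    alpha = 0.5 * (s + sq)
    beta = prod / alpha  # numerically stable companion root
    c0 = d.dose_per_kg / p.vc
    coef_a = c0 * (alpha - p.k21) / (alpha - beta)
    coef_b = c0 * (p.k21 - beta) / (alpha - beta)
    # clip float dust: with k12 = 0 one coefficient is exactly zero analytically
    tol = 1e-12 * c0
    if -tol < coef_a < 0:
        coef_a = 0.0
    if -tol < coef_b < 0:
        coef_b = 0.0
    return MacroParams(coef_a=coef_a, coef_b=coef_b, alpha=alpha, beta=beta)


def micro_from_macro(m: MacroParams, d: DoseRegimen) -> MicroParams:
    """Invert :func:`macro_from_micro`: vc = D/(A+B),
    k21 = (A·beta + B·alpha)/(A+B), k10 = alpha·beta/k21,
    k12 = alpha + beta - k10 - k21."""
    total = m.coef_a + m.coef_b
    vc = d.dose_per_kg / total
    k21 = (m.coef_a * m.beta + m.coef_b * m.alpha) / total
    k10 = m.alpha * m.beta / k21
    k12 = m.alpha + m.beta - k10 - k21
    if -1e-12 * (m.alpha + m.beta) < k12 < 0:
        k12 = 0.0
    return MicroParams(vc=vc, k10=k10, k12=k12, k21=k21)


def predict_concentration(
    p: MicroParams | OneCompParams,
    d: DoseRegimen,
    times_h,
    *,
    subject_id: str = "predicted",
    treatment: str = "meloxicam",
    analyte: str = "meloxicam",
    loq: float = 0.0,
) -> ConcentrationProfile:
    """Closed-form concentration at the requested times (hours).

    Times are measured from the bolus; negative times are rejected.
    """
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("prediction times must be >= 0")
    if isinstance(p, OneCompParams):
        conc = (d.dose_per_kg / p.v) * np.exp(-p.k * t)
    elif isinstance(p, MicroParams):
        m = macro_from_micro(p, d)
        conc = m.coef_a * np.exp(-m.alpha * t) + m.coef_b * np.exp(-m.beta * t)
    else:
        raise TypeError(f"unsupported parameter type {type(p).__name__}")
    return ConcentrationProfile(
        subject_id=subject_id,
        treatment=treatment,
        analyte=analyte,
        times_h=t,
        concentrations=conc,
        loq=loq,
    )


def derived_params(p: MicroParams, d: DoseRegimen) -> DerivedParams:
    """Secondary parameters: Vss = vc(1 + k12/k21), CL = k10·vc,
    half-lives ln2/alpha and ln2/beta, AUC∞ = dose/CL (= A/alpha +
    B/beta), MRT = Vss/CL."""
    m = macro_from_micro(p, d)
    vss = p.vc * (1.0 + p.k12 / p.k21)
    cl = p.k10 * p.vc
    return DerivedParams(
        vss=vss,
        t_half_alpha=_LN2 / m.alpha,
        t_half_beta=_LN2 / m.beta,
        auc_inf=d.dose_per_kg / cl,
        mrt=vss / cl,
        cl=cl,
    )
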