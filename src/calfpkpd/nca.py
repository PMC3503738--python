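"""Non-compartmental summaries and the two-group tests applied to them.

Cmax/Tmax are read directly off the observations (ties broken by the
earliest time); AUC/AUEC uses the linear trapezoidal rule over the
observed window only — no extrapolation beyond sampled times.  The
group comparisons mirror the endpoint table of a two-arm trial:
one-way ANOVA (equivalent to a pooled two-sample t test, F = t²) for
normally distributed summaries and Kruskal–Wallis for Tmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError
from .pk_model import ConcentrationProfile

__all__ = [
    "NCAResult",
    "GroupTestResult",
    "cmax_tmax",
    "auc_linear_trapezoid",
    "nca_summary",
    "compare_groups_anova",
    "compare_groups_kruskal",
]


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start <= self.tmax <= self.t_end:
            raise InvalidParameterError("tmax must lie within [t_start, t_end]")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidParameterError("p_value must be in [0, 1]")


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed value and the earliest time attaining it."""
    if len(profile) == 0:
        raise InsufficientDataError("empty profile")
    idx = int(np.argmax(profile.concentrations))  # argmax returns first maximum
    return float(profile.concentrations[idx]), float(profile.times_h[idx])


def auc_linear_trapezoid(
    profile: ConcentrationProfile, t_start: float, t_end: float
) -> float:
    """Linear-trapezoid area between two *sampled* times.

    Segment areas 0.5·(Cᵢ+Cᵢ₊₁)·(tᵢ₊₁−tᵢ) are accumulated with
    ``math.fsum`` so that splitting the window at an interior sample is
    exactly additive.  Bounds must coincide with observations: the rule
    never extrapolates.
    """
    if not t_start < t_end:
        raise InvalidParameterError("require t_start < t_end")
    t = profile.times_h
    c = profile.concentrations
    i0 = np.searchsorted(t, t_start)
    i1 = np.searchsorted(t, t_end)
    if i0 == len(t) or t[i0] != t_start or i1 == len(t) or t[i1] != t_end:
        raise InvalidParameterError(
            "integration bounds must coincide with sampled times (no extrapolation)"
        )
    seg_t = t[i0 : i1 + 1]
    seg_c = c[i0 : i1 + 1]
    areas = 0.5 * (seg_c[:-1] + seg_c[1:]) * np.diff(seg_t)
    return float(math.fsum(areas.tolist()))


def nca_summary(
    profile: ConcentrationProfile, t_start: float, t_end: float
) -> NCAResult:
    """Cmax/Tmax over the whole profile plus trapezoidal AUC over the window."""
    cmax, tmax = cmax_tmax(profile)
    auc = auc_linear_trapezoid(profile, t_start, t_end)
    return NCAResult(cmax=cmax, tmax=tmax, auc=auc, t_start=min(t_start, tmax), t_end=max(t_end, tmax))


def compare_groups_anova(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """One-way two-group ANOVA; F equals the squared pooled-t statistic,
    p from F(1, n−2).  Degenerate zero-variance inputs use the
    conventions F=0, p=1 (equal means) and F=inf, p=0 (different means).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    ssw = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    if ssw == 0.0:
        if a.mean() == b.mean():
            return GroupTestResult(0.0, 1.0, "anova")
        return GroupTestResult(math.inf, 0.0, "anova")
    f, p = stats.f_oneway(a, b)
    return GroupTestResult(float(f), float(p), "anova")


def compare_groups_kruskal(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """Kruskal–Wallis rank test (mid-rank ties, tie correction), p from
    chi-square with 1 df.  All-identical values yield H=0, p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1 or len(a) + len(b) < 3:
        raise InsufficientDataError("need n >= 1 per group and combined n >= 3")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return GroupTestResult(0.0, 1.0, "kruskal-wallis")
    h, p = stats.kruskal(a, b)
    return GroupTestResult(float(h), float(p), "kruskal-wallis")
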