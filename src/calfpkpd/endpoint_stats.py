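"""Pharmacodynamic, behavior and performance endpoint statistics.

Covers the biomarker analyses (substance P percent change from
baseline, the log10–log10 exposure–response regression, geometric-mean
treatment ratio), accelerometer lying-behavior aggregation with the
pre/post-dehorning contrast, average daily gain, and heart-rate
pre/post window means.

The original trial analysed repeated measures with random-effects mixed
models and the lying proportions with mixed logistic regression; here
those are deliberately replaced by simpler documented contrasts
(pooled two-proportion z tests and a difference-in-differences on the
proportion scale, t-based contrasts on the log scale).  This is a
fidelity limitation, not a claim of equivalence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "EndpointSeries",
    "RegressionFit",
    "GroupContrast",
    "BehaviorHour",
    "BehaviorContrast",
    "WeightRecord",
    "percent_change_from_baseline",
    "loglog_regression",
    "geometric_mean_ratio",
    "adg",
    "lying_proportion",
    "minutes_per_day_difference",
    "prepost_treatment_contrast",
    "hr_prepost_means",
    "HeartRateSeries",
    "PRE_WINDOW_H",
    "POST_WINDOW_H",
]

#: Accelerometer observation windows around dehorning (hour 0).
PRE_WINDOW_H = 48
POST_WINDOW_H = 168

EPOCHS_PER_HOUR = 720  # 5-second epochs


@dataclass(frozen=True)
class EndpointSeries:
    """One subject's endpoint time course; index ``baseline_index``
    marks the sample drawn immediately before dosing."""

    subject_id: str
    treatment: str
    times_h: tuple[float, ...]
    values: tuple[float, ...]
    baseline_index: int = 0

    def __post_init__(self):
        if len(self.times_h) != len(self.values):
            raise InvalidParameterError("times and values must be equal length")
        if not 0 <= self.baseline_index < len(self.values):
            raise InvalidParameterError("baseline_index out of range")

    @property
    def baseline(self) -> float:
        return self.values[self.baseline_index]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise InvalidParameterError("r_squared must be in [0, 1]")
        if self.n_points < 3:
            raise InvalidParameterError("n_points must be >= 3")


@dataclass(frozen=True)
class GroupContrast:
    """Geometric-mean ratio with back-transformed 95% CI."""

    ratio: float
    ci95: tuple[float, float]
    log_scale_se: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise InvalidParameterError("ratio must be > 0")
        if not self.ci95[0] < self.ratio < self.ci95[1]:
            raise InvalidParameterError("CI must bracket the ratio")


@dataclass(frozen=True)
class BehaviorHour:
    """Hourly aggregate of 5-s accelerometer epochs for one calf.

    ``hour`` is indexed relative to dehorning: −48…−1 pre, 0…167 post.
    """

    subject_id: str
    hour: int
    lying: int
    standing: int
    walking: int
    excluded: bool = False

    def __post_init__(self):
        if min(self.lying, self.standing, self.walking) < 0:
            raise InvalidParameterError("epoch counts must be >= 0")
        if self.total > EPOCHS_PER_HOUR:
            raise InvalidParameterError(f"counts exceed {EPOCHS_PER_HOUR} epochs/hour")

    @property
    def total(self) -> int:
        return self.lying + self.standing + self.walking

    @property
    def window(self) -> str:
        return "pre" if self.hour < 0 else "post"


@dataclass(frozen=True)
class WeightRecord:
    subject_id: str
    weight_arrival: float
    weight_pre: float
    weight_post: float
    days_pre: float
    days_post: float
    treatment: str = ""

    def __post_init__(self):
        if min(self.weight_arrival, self.weight_pre, self.weight_post) <= 0:
            raise InvalidParameterError("weights must be > 0")
        if self.days_pre <= 0 or self.days_post <= 0:
            raise InvalidParameterError("day counts must be > 0")


@dataclass(frozen=True)
class HeartRateSeries:
    """15-s sampled heart rate; NaN marks missing intervals."""

    subject_id: str
    treatment: str
    times_h: np.ndarray
    bpm: np.ndarray


def percent_change_from_baseline(s: EndpointSeries) -> EndpointSeries:
    """Map each value to 100·(value − baseline)/baseline.

    Scale-invariant: multiplying the whole series by c > 0 leaves the
    result unchanged.  The baseline point maps to exactly 0.
    """
    if s.baseline <= 0:
        raise InvalidParameterError("baseline must be > 0 for percent change")
    b = s.baseline
    return replace(s, values=tuple(100.0 * (v - b) / b for v in s.values))


def loglog_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of log10(y) on log10(x) with a t-based 95% CI on the slope.

    Pairs with non-positive x or y are dropped (their logarithm is
    undefined); at least 3 valid pairs are required.  Used for the
    drug-concentration vs biomarker-percent-change exposure–response
    curve, hence base 10 to match the conventional reporting scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must be the same length")
    valid = (x > 0) & (y > 0)
    if int(valid.sum()) < 3:
        raise InsufficientDataError(
            f"log-log regression needs >= 3 positive pairs, got {int(valid.sum())}"
        )
    lx, ly = np.log10(x[valid]), np.log10(y[valid])
    n = len(lx)
    if np.ptp(ly) == 0.0:  # constant response: flat line fits perfectly
        return RegressionFit(
            slope=0.0, intercept=float(ly[0]), r_squared=1.0,
            slope_ci95=(0.0, 0.0), n_points=n,
        )
    res = stats.linregress(lx, ly)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * res.stderr
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci95=(float(res.slope - half), float(res.slope + half)),
        n_points=n,
    )


def geometric_mean_ratio(a: Sequence[float], b: Sequence[float]) -> GroupContrast:
    """exp(mean ln a − mean ln b) with a pooled-variance t CI
    back-transformed from the log scale (natural log)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidParameterError("geometric mean requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    diff = la.mean() - lb.mean()
    na, nb = len(a), len(b)
    pooled = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    tcrit = stats.t.ppf(0.975, na + nb - 2)
    return GroupContrast(
        ratio=math.exp(diff),
        ci95=(math.exp(diff - tcrit * se), math.exp(diff + tcrit * se)),
        log_scale_se=se,
    )


def adg(w: WeightRecord) -> tuple[float, float]:
    """Average daily gain before and after dehorning (kg/day):
    (pre − arrival)/days_pre and (post − pre)/days_post."""
    return (
        (w.weight_pre - w.weight_arrival) / w.days_pre,
        (w.weight_post - w.weight_pre) / w.days_post,
    )


def lying_proportion(hours: Sequence[BehaviorHour], window: str) -> float:
    """Pooled lying proportion over non-excluded hours of one window:
    sum of lying epochs over sum of all classified epochs.  This is the
    epoch-count-weighted average of the hourly proportions."""
    if window not in ("pre", "post"):
        raise InvalidParameterError("window must be 'pre' or 'post'")
    usable = [h for h in hours if h.window == window and not h.excluded]
    if not usable:
        raise InsufficientDataError(f"no non-excluded hours in the {window} window")
    lying = sum(h.lying for h in usable)
    total = sum(h.total for h in usable)
    if total == 0:
        raise InsufficientDataError("no classified epochs in window")
    return lying / total


def minutes_per_day_difference(p_pre: float, p_post: float) -> float:
    """Extra standing minutes per day implied by a drop in the lying
    proportion: (p_pre − p_post)·1440.  Antisymmetric in its arguments;
    round to the nearest minute for reporting."""
    for p in (p_pre, p_post):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError("proportions must be in [0, 1]")
    return (p_pre - p_post) * 1440.0


@dataclass(frozen=True)
class BehaviorContrast:
    """Per-group pre/post lying proportions with two-proportion z tests
    and the between-group difference-in-differences."""

    table: pd.DataFrame  # index = group; p_pre, p_post, diff, z, p_value
    did: float
    did_z: float
    did_p: float
    dropped_subjects: tuple[str, ...]


def _pooled_counts(hours: Sequence[BehaviorHour], window: str) -> tuple[int, int]:
    usable = [h for h in hours if h.window == window and not h.excluded]
    return sum(h.lying for h in usable), sum(h.total for h in usable)


def prepost_treatment_contrast(
    hours: Sequence[BehaviorHour],
    treatments: Mapping[str, str],
) -> BehaviorContrast:
    """Pre- vs post-dehorning lying contrast by treatment group.

    Calves missing either window are dropped with a warning (mirroring
    accelerometer loss).  Within each group the pooled epoch counts are
    compared with a two-proportion z test; between groups the
    difference-in-differences (post − pre)_treated − (post − pre)_control
    is tested with a normal approximation on the pooled proportions.
    """
    by_subject: dict[str, list[BehaviorHour]] = {}
    for h in hours:
        by_subject.setdefault(h.subject_id, []).append(h)

    kept: dict[str, list[BehaviorHour]] = {}
    dropped: list[str] = []
    for sid, hs in by_subject.items():
        windows = {h.window for h in hs if not h.excluded}
        if windows >= {"pre", "post"}:
            kept[sid] = hs
        else:
            dropped.append(sid)
            warnings.warn(
                f"calf {sid} lacks a complete pre/post behavior record; dropped",
                stacklevel=2,
            )

    groups: dict[str, list[BehaviorHour]] = {}
    for sid, hs in kept.items():
        groups.setdefault(treatments[sid], []).extend(hs)
    for grp, hs in groups.items():
        if len({h.subject_id for h in hs}) < 2:
            raise InsufficientDataError(f"group {grp!r} has < 2 calves with both windows")
    if len(groups) < 2:
        raise InsufficientDataError("need two treatment groups")

    rows = {}
    var_did = 0.0
    deltas: dict[str, float] = {}
    for grp, hs in sorted(groups.items()):
        ly_pre, n_pre = _pooled_counts(hs, "pre")
        ly_post, n_post = _pooled_counts(hs, "post")
        p_pre, p_post = ly_pre / n_pre, ly_post / n_post
        if ly_pre == ly_post and n_pre == n_post:
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([ly_pre, ly_post], [n_pre, n_post])
            if math.isnan(z):  # identical degenerate proportions
                z, p = 0.0, 1.0
        rows[grp] = {
            "p_pre": p_pre,
            "p_post": p_post,
            "diff": p_post - p_pre,
            "z": float(z),
            "p_value": float(p),
        }
        deltas[grp] = p_post - p_pre
        var_did += p_pre * (1 - p_pre) / n_pre + p_post * (1 - p_post) / n_post

    names = sorted(groups)
    treated = "meloxicam" if "meloxicam" in names else names[-1]
    control = next(g for g in names if g != treated)
    did = deltas[treated] - deltas[control]
    se = math.sqrt(var_did)
    if se == 0.0:
        did_z, did_p = 0.0, 1.0
    else:
        did_z = did / se
        did_p = 2.0 * stats.norm.sf(abs(did_z))
    return BehaviorContrast(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        did=did,
        did_z=did_z,
        did_p=did_p,
        dropped_subjects=tuple(sorted(dropped)),
    )


def hr_prepost_means(
    series: Sequence[HeartRateSeries], dehorn_time_h: float = 0.0
) -> pd.DataFrame:
    """Group mean ± SE heart rate before and after dehorning.

    Per calf the within-window mean skips missing (NaN) samples; calves
    with an empty window are excluded from that window with a warning.
    Returns a frame indexed by (treatment, window) with columns
    mean, se, n_calves.
    """
    records = []
    for s in series:
        for window, mask in (
            ("pre", s.times_h < dehorn_time_h),
            ("post", s.times_h >= dehorn_time_h),
        ):
            vals = s.bpm[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                warnings.warn(
                    f"calf {s.subject_id} has no usable HR samples in the {window} window",
                    stacklevel=2,
                )
                continue
            records.append(
                {
                    "treatment": s.treatment,
                    "window": window,
                    "subject_id": s.subject_id,
                    "mean_bpm": float(np.mean(vals)),
                }
            )
    if not records:
        raise InsufficientDataError("no usable heart-rate data")
    frame = pd.DataFrame(records)
    out = frame.groupby(["treatment", "window"])["mean_bpm"].agg(
        mean="mean",
        se=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0,
        n_calves="count",
    )
    return out
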