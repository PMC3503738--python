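"""Seeded generator of complete synthetic study cohorts.

Emulates the trial design: 12 Holstein calves block-randomized in
weight-matched pairs to IV meloxicam (0.5 mg/kg) or saline placebo,
dehorned at hour 0, with the study sampling schedule (0, 5, 10, 15, 20,
30, 60 min; 6, 22, 30, 45, 52 h), LOQ-censored meloxicam kinetics around
the published population means, a cortisol surge peaking 10–30 min
post-dehorning (identical in both arms), substance P with a treated:control
geometric-mean ratio of 0.5, 15-s heart-rate telemetry elevated over the
first 6 h, hourly lying/standing/walking epoch counts, and body weights
yielding the published average daily gains.

Every random draw comes from a per-(stream, animal) substream spawned
from the master seed, so generating one endpoint never perturbs the
draws of another and identical config + seed reproduce the cohort
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .endpoint_stats import (
    EPOCHS_PER_HOUR,
    POST_WINDOW_H,
    PRE_WINDOW_H,
    BehaviorHour,
    EndpointSeries,
    HeartRateSeries,
    WeightRecord,
)
from .exceptions import InvalidParameterError
from .pk_model import (
    ClearanceParams,
    ConcentrationProfile,
    DoseRegimen,
    micro_from_clearance,
    predict_concentration,
)

__all__ = [
    "StudyConfig",
    "SyntheticCohort",
    "CortisolParams",
    "SPParams",
    "HRParams",
    "BehaviorParams",
    "WeightParams",
    "STUDY_SCHEDULE_H",
    "block_randomize",
    "draw_pk_parameters",
    "generate_pk_profiles",
    "generate_cortisol",
    "generate_sp",
    "generate_hr",
    "generate_behavior",
    "generate_weights",
    "generate_cohort",
]

#: Blood-sampling schedule in hours: pre-dose, 5–60 min, then 6–52 h.
STUDY_SCHEDULE_H = (
    0.0, 5 / 60, 10 / 60, 15 / 60, 20 / 60, 30 / 60, 1.0,
    6.0, 22.0, 30.0, 45.0, 52.0,
)

# RNG substream ids (spawn_key leading element)
_S_RANDOMIZE, _S_PK, _S_CORTISOL, _S_SP, _S_HR, _S_BEHAVIOR, _S_WEIGHTS, _S_ARRIVAL = range(8)


def _rng(seed: int, stream: int, animal: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, animal)))


def _lognormal_mean_preserving(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Lognormal draw whose arithmetic mean equals ``mean`` at coefficient
    of variation ``cv``; degenerates to ``mean`` exactly at cv = 0."""
    if cv == 0.0:
        return mean
    sigma = math.sqrt(math.log1p(cv * cv))
    return mean * math.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma)


@dataclass(frozen=True)
class CortisolParams:
    """Baseline-plus-pulse serum cortisol (nmol/L); the pulse is a
    log-Gaussian bump in time peaking at ``peak_time_h``."""

    baseline: float = 30.0
    peak: float = 160.0
    peak_time_h: float = 0.29  # ~17.5 min, inside the reported 10–30 min window
    width_log: float = 1.0  # SD of the bump on the log-time axis
    noise_cv: float = 0.20


@dataclass(frozen=True)
class SPParams:
    """Plasma substance P (pg/mL): lognormal, stationary in time."""

    control_geomean: float = 114.7
    treatment_ratio: float = 0.5  # treated geometric mean = control × ratio
    cv: float = 0.40


@dataclass(frozen=True)
class HRParams:
    """15-s heart rate (bpm): flat pre-dehorning mean, a step elevation
    over 0–6 h then a smaller one to 12 h, and a treated-arm reduction
    over hours 7–11 (covering the reported 8 and 10 h differences)."""

    pre_mean: float = 91.0
    elevation_0_6h: float = 12.0
    elevation_6_12h: float = 3.0
    treated_reduction_7_11h: float = 6.0
    noise_sd: float = 8.0
    missing_fraction: float = 0.02
    window_h: float = 48.0  # recorded for ±window_h around dehorning
    sample_interval_h: float = 15.0 / 3600.0


@dataclass(frozen=True)
class BehaviorParams:
    """Hourly lying/standing/walking epoch counts (720 epochs/hour)."""

    lying_pre_control: float = 0.461
    lying_post_control: float = 0.427
    lying_pre_treated: float = 0.431
    lying_post_treated: float = 0.430
    walking_fraction: float = 0.10  # of non-lying epochs
    sample_epochs: bool = True  # False: deterministic round(720·p) counts
    dropout: bool = False  # emulate one treated calf's accelerometer failure
    excluded_hours: tuple[int, ...] = (-24, 0, 24, 48, 72, 96, 120, 144)


@dataclass(frozen=True)
class WeightParams:
    """Body weights (kg) and average daily gains (kg/day)."""

    arrival_mean: float = 170.0
    arrival_sd: float = 15.0
    arrival_range: tuple[float, float] = (140.0, 205.0)
    adg_pre_mean: float = 0.9
    adg_pre_sd: float = 0.2
    adg_post_treated: float = 1.05
    adg_post_control: float = 0.40
    adg_post_sd_treated: float = 0.32
    adg_post_sd_control: float = 0.61
    days_pre: float = 19.0
    days_post: float = 10.0


@dataclass(frozen=True)
class StudyConfig:
    """Study design and effect sizes for cohort simulation."""

    n_per_group: int = 6
    dose_per_kg: float = 500.0  # µg/kg
    sampling_schedule_h: tuple[float, ...] = STUDY_SCHEDULE_H
    pk_population_means: ClearanceParams = field(
        default_factory=lambda: ClearanceParams(vc=94.88, cl=6.64, cld2=225.18, v2=99.07)
    )
    pk_bsv_cv: float = 0.20
    residual_cv: float = 0.15
    loq: float = 0.025  # µg/mL
    cortisol: CortisolParams = field(default_factory=CortisolParams)
    sp: SPParams = field(default_factory=SPParams)
    hr: HRParams = field(default_factory=HRParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    weights: WeightParams = field(default_factory=WeightParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if min(self.pk_bsv_cv, self.residual_cv, self.loq) < 0:
            raise InvalidParameterError("CVs and LOQ must be >= 0")
        sched = np.asarray(self.sampling_schedule_h)
        if np.any(np.diff(sched) <= 0):
            raise InvalidParameterError("sampling schedule must be strictly increasing")
        for p in (
            self.behavior.lying_pre_control,
            self.behavior.lying_post_control,
            self.behavior.lying_pre_treated,
            self.behavior.lying_post_treated,
        ):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("lying proportions must be in [0, 1]")

    @property
    def dose(self) -> DoseRegimen:
        return DoseRegimen(dose_per_kg=self.dose_per_kg)

    def subject_ids(self) -> list[str]:
        return [f"calf{i + 1:02d}" for i in range(2 * self.n_per_group)]


@dataclass
class SyntheticCohort:
    """A full simulated study: assignments plus every endpoint table."""

    config: StudyConfig
    assignments: dict[str, str]  # subject_id -> "meloxicam" | "control"
    arrival_weights: dict[str, float]
    pk_profiles: list[ConcentrationProfile] = field(default_factory=list)
    cortisol: list[EndpointSeries] = field(default_factory=list)
    sp: list[EndpointSeries] = field(default_factory=list)
    hr: list[HeartRateSeries] = field(default_factory=list)
    behavior: list[BehaviorHour] = field(default_factory=list)
    weights: list[WeightRecord] = field(default_factory=list)


def block_randomize(weights: Sequence[float], seed) -> np.ndarray:
    """Weight-matched pair randomization.

    Animals are ranked by ascending weight and blocked in consecutive
    pairs; within each pair every calf receives an independent uniform
    draw and the higher draw goes to the meloxicam arm.  Returns labels
    aligned with the input order; exactly half per arm.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    if n % 2 != 0:
        raise InvalidParameterError("block randomization requires an even number of animals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = np.argsort(weights, kind="stable")
    labels = np.empty(n, dtype=object)
    for pair_start in range(0, n, 2):
        i, j = order[pair_start], order[pair_start + 1]
        u_i, u_j = rng.uniform(), rng.uniform()
        if u_i > u_j:
            labels[i], labels[j] = "meloxicam", "control"
        else:
            labels[i], labels[j] = "control", "meloxicam"
    return labels


def _draw_arrival_weights(cfg: StudyConfig, subject_ids: Sequence[str]) -> dict[str, float]:
    wp = cfg.weights
    out = {}
    for idx, sid in enumerate(subject_ids):
        rng = _rng(cfg.seed, _S_ARRIVAL, idx)
        w = rng.normal(wp.arrival_mean, wp.arrival_sd) if wp.arrival_sd > 0 else wp.arrival_mean
        out[sid] = float(np.clip(w, *wp.arrival_range))
    return out


def _assign(cfg: StudyConfig) -> tuple[dict[str, str], dict[str, float]]:
    sids = cfg.subject_ids()
    arrivals = _draw_arrival_weights(cfg, sids)
    labels = block_randomize([arrivals[s] for s in sids], _rng(cfg.seed, _S_RANDOMIZE))
    return dict(zip(sids, labels)), arrivals


def draw_pk_parameters(
    cfg: StudyConfig, animal_idx: int, rng: np.random.Generator | None = None
) -> ClearanceParams:
    """The clearance-family parameter set simulated for one animal:
    each of Vc, CL, CLD2, V2 drawn independently lognormally
    (mean-preserving) around the population means at the configured
    between-subject CV.  Deterministic per (seed, animal index)."""
    rng = rng if rng is not None else _rng(cfg.seed, _S_PK, animal_idx)
    pm = cfg.pk_population_means
    return ClearanceParams(
        vc=_lognormal_mean_preserving(pm.vc, cfg.pk_bsv_cv, rng),
        cl=_lognormal_mean_preserving(pm.cl, cfg.pk_bsv_cv, rng),
        cld2=_lognormal_mean_preserving(pm.cld2, cfg.pk_bsv_cv, rng),
        v2=_lognormal_mean_preserving(pm.v2, cfg.pk_bsv_cv, rng),
    )


def generate_pk_profiles(
    cfg: StudyConfig, assignments: Mapping[str, str]
) -> list[ConcentrationProfile]:
    """Meloxicam plasma profiles at the study schedule.

    Treated animals get per-animal clearance-family parameters drawn
    lognormally (mean-preserving) around the population means, a
    proportional residual error, and LOQ censoring; the pre-dose t = 0
    sample is zero.  Control animals are entirely BLOQ.
    """
    times = np.asarray(cfg.sampling_schedule_h)
    profiles = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        rng = _rng(cfg.seed, _S_PK, idx)
        if arm != "meloxicam":
            conc = np.zeros_like(times)
        else:
            cp = draw_pk_parameters(cfg, idx, rng)
            pred = predict_concentration(micro_from_clearance(cp), cfg.dose, times)
            conc = pred.concentrations.copy()
            conc[times <= cfg.dose.admin_time_h] = 0.0  # pre-dose sample
            if cfg.residual_cv > 0:
                conc = conc * (1.0 + cfg.residual_cv * rng.standard_normal(len(times)))
                conc = np.clip(conc, 0.0, None)
        profiles.append(
            ConcentrationProfile(
                subject_id=sid,
                treatment=arm,
                analyte="meloxicam",
                times_h=times,
                concentrations=conc,
                loq=cfg.loq,
            )
        )
    return profiles


def _cortisol_mean(t: np.ndarray, p: CortisolParams) -> np.ndarray:
    out = np.full_like(t, p.baseline, dtype=float)
    post = t > 0
    lt = np.log(t[post] / p.peak_time_h)
    out[post] = p.baseline + (p.peak - p.baseline) * np.exp(-(lt**2) / (2 * p.width_log**2))
    return out


def generate_cortisol(
    cfg: StudyConfig, assignments: Mapping[str, str]
) -> list[EndpointSeries]:
    """Serum cortisol at the study schedule: identical baseline-plus-pulse
    distributions in both arms (no treatment effect), lognormal noise."""
    times = np.asarray(cfg.sampling_schedule_h)
    mean = _cortisol_mean(times, cfg.cortisol)
    series = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        rng = _rng(cfg.seed, _S_CORTISOL, idx)
        vals = np.array(
            [_lognormal_mean_preserving(m, cfg.cortisol.noise_cv, rng) for m in mean]
        )
        series.append(
            EndpointSeries(
                subject_id=sid,
                treatment=arm,
                times_h=tuple(times),
                values=tuple(vals),
                baseline_index=0,
            )
        )
    return series


def generate_sp(cfg: StudyConfig, assignments: Mapping[str, str]) -> list[EndpointSeries]:
    """Plasma substance P: stationary lognormal values; the treated arm's
    geometric mean is the control geometric mean times the configured
    ratio (0.5 reproduces the published contrast)."""
    times = np.asarray(cfg.sampling_schedule_h)
    sigma = math.sqrt(math.log1p(cfg.sp.cv**2)) if cfg.sp.cv > 0 else 0.0
    series = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        rng = _rng(cfg.seed, _S_SP, idx)
        gm = cfg.sp.control_geomean * (cfg.sp.treatment_ratio if arm == "meloxicam" else 1.0)
        vals = gm * np.exp(sigma * rng.standard_normal(len(times)))
        series.append(
            EndpointSeries(
                subject_id=sid,
                treatment=arm,
                times_h=tuple(times),
                values=tuple(float(v) for v in vals),
                baseline_index=0,
            )
        )
    return series


def generate_hr(cfg: StudyConfig, assignments: Mapping[str, str]) -> list[HeartRateSeries]:
    """15-s heart-rate series over ±window_h around dehorning."""
    p = cfg.hr
    n_side = int(round(p.window_h / p.sample_interval_h))
    t = np.arange(-n_side, n_side) * p.sample_interval_h
    base = np.full_like(t, p.pre_mean)
    base[(t >= 0) & (t < 6)] += p.elevation_0_6h
    base[(t >= 6) & (t < 12)] += p.elevation_6_12h
    series = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        rng = _rng(cfg.seed, _S_HR, idx)
        bpm = base.copy()
        if arm == "meloxicam":
            bpm[(t >= 7) & (t < 11)] -= p.treated_reduction_7_11h
        if p.noise_sd > 0:
            bpm = bpm + p.noise_sd * rng.standard_normal(len(t))
        if p.missing_fraction > 0:
            bpm[rng.uniform(size=len(t)) < p.missing_fraction] = np.nan
        series.append(HeartRateSeries(subject_id=sid, treatment=arm, times_h=t, bpm=bpm))
    return series


def generate_behavior(
    cfg: StudyConfig, assignments: Mapping[str, str]
) -> list[BehaviorHour]:
    """Hourly epoch counts over 48 h pre and 168 h post dehorning.

    Each hour's lying count is Binomial(720, p) with the window- and
    arm-specific lying probability (deterministic round(720·p) when
    ``sample_epochs`` is off); non-lying epochs split between walking
    and standing.  Configured intervention hours are flagged excluded;
    with ``dropout`` on, the first treated calf loses all records.
    """
    b = cfg.behavior
    hours = list(range(-PRE_WINDOW_H, POST_WINDOW_H))
    excluded = set(b.excluded_hours)
    dropout_sid = None
    if b.dropout:
        dropout_sid = next(s for s, a in assignments.items() if a == "meloxicam")
    records = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        if sid == dropout_sid:
            continue
        rng = _rng(cfg.seed, _S_BEHAVIOR, idx)
        for h in hours:
            if arm == "meloxicam":
                p_lie = b.lying_pre_treated if h < 0 else b.lying_post_treated
            else:
                p_lie = b.lying_pre_control if h < 0 else b.lying_post_control
            if b.sample_epochs:
                lying = int(rng.binomial(EPOCHS_PER_HOUR, p_lie))
                walking = int(rng.binomial(EPOCHS_PER_HOUR - lying, b.walking_fraction))
            else:
                lying = round(EPOCHS_PER_HOUR * p_lie)
                walking = round((EPOCHS_PER_HOUR - lying) * b.walking_fraction)
            records.append(
                BehaviorHour(
                    subject_id=sid,
                    hour=h,
                    lying=lying,
                    standing=EPOCHS_PER_HOUR - lying - walking,
                    walking=walking,
                    excluded=h in excluded,
                )
            )
    return records


def generate_weights(
    cfg: StudyConfig, assignments: Mapping[str, str]
) -> list[WeightRecord]:
    """Arrival, pre- and post-dehorning body weights implying the
    configured arm-specific average daily gains."""
    wp = cfg.weights
    arrivals = _draw_arrival_weights(cfg, list(assignments))
    records = []
    for idx, (sid, arm) in enumerate(assignments.items()):
        rng = _rng(cfg.seed, _S_WEIGHTS, idx)
        adg_pre = wp.adg_pre_mean + (wp.adg_pre_sd * rng.standard_normal() if wp.adg_pre_sd else 0.0)
        if arm == "meloxicam":
            mu, sd = wp.adg_post_treated, wp.adg_post_sd_treated
        else:
            mu, sd = wp.adg_post_control, wp.adg_post_sd_control
        adg_post = mu + (sd * rng.standard_normal() if sd else 0.0)
        w_arr = arrivals[sid]
        w_pre = w_arr + adg_pre * wp.days_pre
        w_post = w_pre + adg_post * wp.days_post
        records.append(
            WeightRecord(
                subject_id=sid,
                treatment=arm,
                weight_arrival=w_arr,
                weight_pre=w_pre,
                weight_post=w_post,
                days_pre=wp.days_pre,
                days_post=wp.days_post,
            )
        )
    return records


_ALL_ENDPOINTS = ("pk", "cortisol", "sp", "hr", "behavior", "weights")


def generate_cohort(
    cfg: StudyConfig, include: Sequence[str] = _ALL_ENDPOINTS
) -> SyntheticCohort:
    """Assemble a full cohort: draw arrival weights, block-randomize,
    then generate the requested endpoint tables (all by default)."""
    unknown = set(include) - set(_ALL_ENDPOINTS)
    if unknown:
        raise InvalidParameterError(f"unknown endpoints {sorted(unknown)}")
    assignments, arrivals = _assign(cfg)
    cohort = SyntheticCohort(config=cfg, assignments=assignments, arrival_weights=arrivals)
    if "pk" in include:
        cohort.pk_profiles = generate_pk_profiles(cfg, assignments)
    if "cortisol" in include:
        cohort.cortisol = generate_cortisol(cfg, assignments)
    if "sp" in include:
        cohort.sp = generate_sp(cfg, assignments)
    if "hr" in include:
        cohort.hr = generate_hr(cfg, assignments)
    if "behavior" in include:
        cohort.behavior = generate_behavior(cfg, assignments)
    if "weights" in include:
        cohort.weights = generate_weights(cfg, assignments)
    return cohort
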