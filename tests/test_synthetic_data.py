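import dataclasses
import math

import numpy as np
import pytest

from calfpkpd.endpoint_stats import (
    adg,
    geometric_mean_ratio,
    hr_prepost_means,
    lying_proportion,
)
from calfpkpd.exceptions import InvalidParameterError
from calfpkpd.pk_fit import fit_compartmental
from calfpkpd.pk_model import micro_from_clearance, predict_concentration
from calfpkpd.synthetic_data import (
    BehaviorParams,
    CortisolParams,
    HRParams,
    SPParams,
    StudyConfig,
    WeightParams,
    block_randomize,
    draw_pk_parameters,
    generate_behavior,
    generate_cohort,
    generate_cortisol,
    generate_hr,
    generate_pk_profiles,
    generate_sp,
    generate_weights,
)


def small_hr():
    return HRParams(window_h=1.0)  # keep the 15-s series short in tests


class TestBlockRandomize:
    def test_twelve_calves_six_per_arm_paired_by_weight(self):
        rng = np.random.default_rng(0)
        weights = rng.uniform(140, 205, 12)
        labels = block_randomize(weights, seed=5)
        assert sum(labels == "meloxicam") == 6
        assert sum(labels == "control") == 6
        order = np.argsort(weights, kind="stable")
        for k in range(0, 12, 2):  # adjacent-weight pairs split across arms
            assert {labels[order[k]], labels[order[k + 1]]} == {"meloxicam", "control"}

    def test_two_animals_one_each(self):
        labels = block_randomize([150.0, 160.0], seed=1)
        assert set(labels) == {"meloxicam", "control"}

    def test_deterministic_given_seed(self):
        weights = list(range(140, 164, 2))
        a = block_randomize(weights, seed=9)
        b = block_randomize(weights, seed=9)
        assert list(a) == list(b)

    def test_odd_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            block_randomize([1.0, 2.0, 3.0], seed=0)


class TestDeterminism:
    def test_same_config_and_seed_bit_identical(self):
        cfg = StudyConfig(seed=21, hr=small_hr())
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.assignments == b.assignments
        for pa, pb in zip(a.pk_profiles, b.pk_profiles):
            assert pa == pb
        assert [h for h in a.behavior] == [h for h in b.behavior]
        assert a.weights == b.weights
        for sa, sb in zip(a.hr, b.hr):
            np.testing.assert_array_equal(sa.bpm, sb.bpm)

    def test_endpoint_subsets_do_not_perturb_draws(self):
        cfg = StudyConfig(seed=21, hr=small_hr())
        full = generate_cohort(cfg)
        pk_only = generate_cohort(cfg, include=("pk",))
        for pa, pb in zip(full.pk_profiles, pk_only.pk_profiles):
            assert pa == pb


class TestPKGeneration:
    def test_noise_off_profiles_equal_population_prediction(self, dose, schedule):
        cfg = StudyConfig(seed=1, pk_bsv_cv=0.0, residual_cv=0.0)
        cohort = generate_cohort(cfg, include=("pk",))
        expected = predict_concentration(
            micro_from_clearance(cfg.pk_population_means), dose, schedule
        )
        treated = [p for p in cohort.pk_profiles if p.treatment == "meloxicam"]
        assert len(treated) == 6
        for p in treated:
            np.testing.assert_allclose(
                p.concentrations[1:], expected.concentrations[1:], rtol=1e-12
            )
            assert p.concentrations[0] == 0.0  # pre-dose sample

    def test_control_arm_has_no_quantifiable_points(self):
        cfg = StudyConfig(seed=2)
        cohort = generate_cohort(cfg, include=("pk",))
        for p in cohort.pk_profiles:
            if p.treatment == "control":
                assert p.n_quantifiable == 0

    def test_noise_off_round_trip_through_fit(self, dose):
        cfg = StudyConfig(seed=3, pk_bsv_cv=0.20, residual_cv=0.0)
        cohort = generate_cohort(cfg, include=("pk",))
        treated_idx = [
            i for i, sid in enumerate(cohort.assignments)
            if cohort.assignments[sid] == "meloxicam"
        ]
        profile = next(p for p in cohort.pk_profiles if p.treatment == "meloxicam")
        idx = list(cohort.assignments).index(profile.subject_id)
        truth = draw_pk_parameters(cfg, idx)
        fit = fit_compartmental(profile, dose, n_compartments=2)
        cl_fit = fit.params.k10 * fit.params.vc
        assert cl_fit == pytest.approx(truth.cl, rel=1e-3)
        assert fit.params.vc == pytest.approx(truth.vc, rel=1e-3)

    def test_loq_censoring_flags_low_values(self):
        cfg = StudyConfig(seed=4, loq=1.0)  # absurdly high LOQ
        cohort = generate_cohort(cfg, include=("pk",))
        for p in cohort.pk_profiles:
            assert np.all(p.bloq == (p.concentrations < 1.0))


class TestCortisol:
    def test_noise_off_peaks_at_configured_time(self, schedule):
        cfg = StudyConfig(seed=5, cortisol=CortisolParams(noise_cv=0.0))
        series = generate_cortisol(cfg, {"a": "control", "b": "meloxicam"})
        vals = np.asarray(series[0].values)
        # peak lands on the grid point nearest 0.29 h, inside 10-30 min
        t_peak = series[0].times_h[int(np.argmax(vals))]
        assert 10 / 60 <= t_peak <= 30 / 60
        assert vals.max() == pytest.approx(160.0, rel=0.05)
        assert vals[0] == pytest.approx(30.0)  # baseline at t=0
        # identical distributions in both arms
        np.testing.assert_allclose(series[0].values, series[1].values)

    def test_baseline_only_config_is_flat(self):
        cfg = StudyConfig(seed=6, cortisol=CortisolParams(baseline=30, peak=30, noise_cv=0.0))
        series = generate_cortisol(cfg, {"a": "control"})
        assert np.ptp(np.asarray(series[0].values)) == pytest.approx(0.0, abs=1e-12)

    def test_group_cmax_means_recover_config(self):
        cfg = StudyConfig(seed=7, cortisol=CortisolParams(noise_cv=0.05))
        cohort = generate_cohort(cfg, include=("cortisol",))
        cmax = [max(s.values) for s in cohort.cortisol]
        assert np.mean(cmax) == pytest.approx(160.0, rel=0.10)


class TestSubstanceP:
    def test_noise_off_exact_geometric_means(self):
        cfg = StudyConfig(seed=8, sp=SPParams(cv=0.0))
        series = generate_sp(cfg, {"a": "control", "b": "meloxicam"})
        assert np.asarray(series[0].values) == pytest.approx(114.7)
        assert np.asarray(series[1].values) == pytest.approx(114.7 * 0.5)

    def test_ratio_recovered_within_mc_tolerance(self):
        cfg = StudyConfig(seed=9, n_per_group=50, sp=SPParams(cv=0.40))
        cohort = generate_cohort(cfg, include=("sp",))
        gm = {"meloxicam": [], "control": []}
        for s in cohort.sp:
            gm[s.treatment].append(float(np.exp(np.mean(np.log(s.values)))))
        res = geometric_mean_ratio(gm["meloxicam"], gm["control"])
        assert abs(math.log(res.ratio) - math.log(0.5)) < 3 * res.log_scale_se

    def test_null_ratio_ci_covers_one(self):
        cfg = StudyConfig(seed=10, sp=SPParams(treatment_ratio=1.0, cv=0.3))
        cohort = generate_cohort(cfg, include=("sp",))
        gm = {"meloxicam": [], "control": []}
        for s in cohort.sp:
            gm[s.treatment].append(float(np.exp(np.mean(np.log(s.values)))))
        res = geometric_mean_ratio(gm["meloxicam"], gm["control"])
        assert res.ci95[0] < 1.0 < res.ci95[1]


class TestHeartRate:
    def test_noise_off_pre_mean_equals_config(self):
        cfg = StudyConfig(seed=11, hr=HRParams(noise_sd=0.0, missing_fraction=0.0,
                                               window_h=12.0))
        series = generate_hr(cfg, {"a": "control"})
        s = series[0]
        assert np.mean(s.bpm[s.times_h < 0]) == pytest.approx(91.0)
        assert np.all(s.bpm[(s.times_h >= 0) & (s.times_h < 6)] == 103.0)

    def test_treated_reduction_window(self):
        cfg = StudyConfig(seed=12, hr=HRParams(noise_sd=0.0, missing_fraction=0.0,
                                               window_h=12.0))
        series = generate_hr(cfg, {"a": "control", "b": "meloxicam"})
        ctrl, mel = series
        sel = (ctrl.times_h >= 8) & (ctrl.times_h < 10)
        assert np.all(ctrl.bpm[sel] - mel.bpm[sel] == 6.0)

    def test_prepost_means_recover_config(self):
        cfg = StudyConfig(seed=13, hr=HRParams(noise_sd=8.0, window_h=6.0))
        cohort = generate_cohort(cfg, include=("hr",))
        table = hr_prepost_means(cohort.hr)
        pre = table.xs("pre", level="window")
        for arm in ("control", "meloxicam"):
            assert abs(pre.loc[arm, "mean"] - 91.0) < 3 * max(pre.loc[arm, "se"], 0.2)

    def test_full_missingness_excludes_calf_with_warning(self):
        cfg = StudyConfig(seed=14, hr=HRParams(missing_fraction=1.0, window_h=0.5))
        cohort = generate_cohort(cfg, include=("hr",))
        with pytest.warns(UserWarning):
            with pytest.raises(Exception):
                hr_prepost_means(cohort.hr)


class TestBehavior:
    def test_probability_one_all_lying(self):
        cfg = StudyConfig(
            seed=15,
            behavior=BehaviorParams(
                lying_pre_control=1.0, lying_post_control=1.0,
                lying_pre_treated=1.0, lying_post_treated=1.0,
                walking_fraction=0.0,
            ),
        )
        hours = generate_behavior(cfg, {"a": "control"})
        assert all(h.lying == 720 for h in hours)

    def test_deterministic_counts_invert_through_lying_proportion(self):
        cfg = StudyConfig(seed=16, behavior=BehaviorParams(sample_epochs=False,
                                                           excluded_hours=()))
        hours = generate_behavior(cfg, {"a": "control", "b": "meloxicam"})
        ctrl = [h for h in hours if h.subject_id == "a"]
        assert lying_proportion(ctrl, "pre") == pytest.approx(0.461, abs=1e-3)
        assert lying_proportion(ctrl, "post") == pytest.approx(0.427, abs=1e-3)

    def test_sampled_proportions_within_mc_tolerance(self):
        cfg = StudyConfig(seed=17, n_per_group=100,
                          behavior=BehaviorParams(excluded_hours=()))
        cohort = generate_cohort(cfg, include=("behavior",))
        ctrl = [h for h in cohort.behavior
                if cohort.assignments[h.subject_id] == "control"]
        p = lying_proportion(ctrl, "pre")
        n = 100 * 48 * 720
        se = math.sqrt(0.461 * (1 - 0.461) / n)
        assert abs(p - 0.461) < 3 * se

    def test_dropout_removes_exactly_one_treated_calf(self):
        cfg = StudyConfig(seed=18, behavior=BehaviorParams(dropout=True))
        cohort = generate_cohort(cfg, include=("behavior",))
        present = {h.subject_id for h in cohort.behavior}
        missing = set(cohort.assignments) - present
        assert len(missing) == 1
        assert cohort.assignments[missing.pop()] == "meloxicam"

    def test_excluded_hours_flagged(self):
        cfg = StudyConfig(seed=19, behavior=BehaviorParams(excluded_hours=(0, 24)))
        hours = generate_behavior(cfg, {"a": "control"})
        flagged = {h.hour for h in hours if h.excluded}
        assert flagged == {0, 24}


class TestWeights:
    def test_noise_off_adg_exactly_config(self):
        wp = WeightParams(arrival_sd=0.0, adg_pre_sd=0.0,
                          adg_post_sd_treated=0.0, adg_post_sd_control=0.0)
        cfg = StudyConfig(seed=20, weights=wp)
        records = generate_weights(cfg, {"a": "control", "b": "meloxicam"})
        by_arm = {r.treatment: adg(r) for r in records}
        assert by_arm["control"] == (pytest.approx(0.9), pytest.approx(0.40))
        assert by_arm["meloxicam"] == (pytest.approx(0.9), pytest.approx(1.05))

    def test_group_difference_recovered_within_mc_tolerance(self):
        cfg = StudyConfig(seed=22, n_per_group=200)
        cohort = generate_cohort(cfg, include=("weights",))
        post = {"meloxicam": [], "control": []}
        for r in cohort.weights:
            post[r.treatment].append(adg(r)[1])
        diff = np.mean(post["meloxicam"]) - np.mean(post["control"])
        se = math.sqrt(np.var(post["meloxicam"], ddof=1) / 200
                       + np.var(post["control"], ddof=1) / 200)
        assert abs(diff - 0.65) < 3 * se

    def test_arrival_weights_within_study_range(self):
        cfg = StudyConfig(seed=23, n_per_group=50)
        cohort = generate_cohort(cfg, include=("weights",))
        for r in cohort.weights:
            assert 140.0 <= r.weight_arrival <= 205.0
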