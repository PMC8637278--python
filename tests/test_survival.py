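import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stepscore.survival as sv
from stepscore import (CohortRecord, abs_permutation_test, cox_fit,
                       group_compare, hr_landmark, hr_virtual_endpoints,
                       km_estimate, ph_check_schoenfeld, stepwise_select,
                       youden_cutpoint_kernel)


def sim_cohort(rng, n, beta=0.0, rate=0.1, censor=10.0, x=None):
    """Exponential PH data frame with a single covariate ``x``."""
    if x is None:
        x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    obs = np.minimum(t, censor)
    return pd.DataFrame({"x": x, "time_years": obs, "event": (t <= censor).astype(int)})


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # 1+ censored, two events at 2, 3+ censored
        km = km_estimate([1, 2, 2, 3], [0, 1, 1, 0])
        assert km(2) == pytest.approx(1 / 3)
        assert km(1.5) == 1.0
        assert km(9) == pytest.approx(1 / 3)

    def test_no_events_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km(0) == km(5) == 1.0

    def test_distinct_event_times_reduce_to_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0]
        km = km_estimate(times, [1, 1, 1, 1])
        for i, t in enumerate(times):
            assert km(t) == pytest.approx(1 - (i + 1) / 4)

    def test_monotone_right_continuous_from_one(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rng.exponential(2, 100), rng.binomial(1, 0.7, 100))
        grid = np.linspace(0, 10, 200)
        s = km(grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        t = rng.exponential(3, 150)
        e = rng.binomial(1, 0.6, 150)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0.01, t.max(), 50)
        ours = km(grid)
        theirs = np.asarray(kmf.survival_function_at_times(grid))
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestCoxFit:
    def test_recovers_hr_two_on_large_sample(self):
        df = sim_cohort(np.random.default_rng(1), 2000, beta=np.log(2))
        eff = cox_fit(df, ["x"]).effects["x"]
        assert 1.8 <= eff.hr <= 2.2
        assert eff.ci_low <= eff.hr <= eff.ci_high

    def test_duplicated_dataset_same_point_estimate(self):
        df = sim_cohort(np.random.default_rng(2), 300, beta=0.5)
        h1 = cox_fit(df, ["x"]).effects["x"].hr
        h2 = cox_fit(pd.concat([df, df], ignore_index=True), ["x"]).effects["x"].hr
        # identical in exact arithmetic; bounded by the optimizer's stopping rule
        assert h1 == pytest.approx(h2, rel=2e-3)

    def test_null_coverage_of_unit_hr(self):
        rng = np.random.default_rng(3)
        cover = 0
        for _ in range(40):
            eff = cox_fit(sim_cohort(rng, 300, beta=0.0), ["x"]).effects["x"]
            cover += eff.ci_low <= 1.0 <= eff.ci_high
        assert cover >= 33  # ~95% nominal; loose binomial bound

    def test_listwise_missing_dropped(self):
        df = sim_cohort(np.random.default_rng(4), 200, beta=0.3)
        df.loc[:9, "x"] = np.nan
        assert cox_fit(df, ["x"]).n == 190

    def test_too_few_events_raises(self):
        df = pd.DataFrame({"x": [0, 1, 0], "time_years": [1, 2, 3],
                           "event": [1, 0, 0]})
        with pytest.raises(sv.SurvivalError):
            cox_fit(df, ["x"])

    def test_time_transform_term_null_under_ph(self):
        df = sim_cohort(np.random.default_rng(5), 800, beta=np.log(2))
        fit = cox_fit(df, ["x"], time_transform={"x": np.log1p})
        assert set(fit.effects) == {"x", "x_tt"}
        # under proportional hazards the time-interaction is consistent with 0
        assert fit.effects["x_tt"].p > 0.01


class TestSchoenfeld:
    def test_ph_data_not_flagged(self):
        df = sim_cohort(np.random.default_rng(6), 800, beta=np.log(2))
        p = ph_check_schoenfeld(cox_fit(df, ["x"]))["x"]
        assert p > 0.05

    def test_sign_flip_effect_is_flagged(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = rng.binomial(1, 0.5, n).astype(float)
        beta = 1.0
        # hazard exp(+beta x) before t=5, exp(-beta x) after
        r1, r2 = 0.1 * np.exp(beta * x), 0.1 * np.exp(-beta * x)
        t1 = rng.exponential(1 / r1)
        t = np.where(t1 < 5, t1, 5 + rng.exponential(1 / r2))
        obs = np.minimum(t, 10.0)
        df = pd.DataFrame({"x": x, "time_years": obs, "event": (t <= 10).astype(int)})
        p = ph_check_schoenfeld(cox_fit(df, ["x"]))["x"]
        assert p < 0.05


class TestStepwise:
    def test_strong_predictor_retained_noise_rejected(self):
        rng = np.random.default_rng(8)
        df = sim_cohort(rng, 800, beta=np.log(2))
        for j in range(3):
            df[f"noise{j}"] = rng.normal(size=len(df))
        model = stepwise_select(df, ["noise0", "x", "noise1", "noise2"])
        assert "x" in model.variables

    def test_empty_candidates_give_empty_model(self):
        df = sim_cohort(np.random.default_rng(9), 100, beta=0.0)
        assert stepwise_select(df, []).variables == ()

    def test_all_noise_often_empty(self):
        rng = np.random.default_rng(10)
        df = sim_cohort(rng, 300, beta=0.0)
        df["noise"] = rng.normal(size=len(df))
        model = stepwise_select(df, ["noise"], sle=0.01, sls=0.01)
        assert model.variables in ((), ("noise",))


class TestYouden:
    def test_two_normals_optimum_near_midpoint(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(2, 1, 2000)])
        labels = np.array([False] * 2000 + [True] * 2000)
        res = youden_cutpoint_kernel(scores, labels)
        assert res.cutoff == pytest.approx(1.0, abs=0.15)
        assert res.youden_j == pytest.approx(2 * stats.norm.cdf(1) - 1, abs=0.05)

    def test_identical_distributions_give_small_j(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert youden_cutpoint_kernel(scores, labels).youden_j < 0.1

    def test_perfect_separation_approaches_one(self):
        scores = np.concatenate([np.random.default_rng(13).normal(0, 0.1, 500),
                                 np.random.default_rng(14).normal(10, 0.1, 500)])
        labels = np.array([False] * 500 + [True] * 500)
        assert youden_cutpoint_kernel(scores, labels).youden_j > 0.99

    def test_degenerate_class_raises(self):
        with pytest.raises(sv.SurvivalError):
            youden_cutpoint_kernel([1.0, 2.0], [True, True])


class TestAbsPermutation:
    def _two_groups(self, rng, n=150, ratio=1.0):
        g = np.repeat([0, 1], n)
        rate = np.where(g == 0, 0.15, 0.15 * ratio)
        t = rng.exponential(1 / rate)
        obs = np.minimum(t, 10.0)
        return obs, (t <= 10).astype(int), g

    def test_identical_samples_give_zero_statistic(self):
        times = [1, 2, 3, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = abs_permutation_test(times, events, g, n_perm=50, seed=1)
        assert res.statistic == 0.0

    def test_statistic_symmetric_under_relabeling(self):
        rng = np.random.default_rng(15)
        t, e, g = self._two_groups(rng, ratio=2.0)
        s1 = abs_permutation_test(t, e, g, n_perm=10, seed=3).statistic
        s2 = abs_permutation_test(t, e, 1 - g, n_perm=10, seed=3).statistic
        assert s1 == pytest.approx(s2)

    def test_same_seed_same_p(self):
        rng = np.random.default_rng(16)
        t, e, g = self._two_groups(rng, ratio=2.0)
        p1 = abs_permutation_test(t, e, g, n_perm=200, seed=5).p_value
        p2 = abs_permutation_test(t, e, g, n_perm=200, seed=5).p_value
        assert p1 == p2

    def test_fourfold_hazard_detected(self):
        rng = np.random.default_rng(17)
        t, e, g = self._two_groups(rng, n=200, ratio=4.0)
        assert abs_permutation_test(t, e, g, n_perm=200, seed=7).p_value < 0.05

    def test_single_group_without_event_raises(self):
        with pytest.raises(sv.SurvivalError):
            abs_permutation_test([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1],
                                 n_perm=10, seed=1)


class TestHrCurves:
    def test_virtual_endpoint_at_cap_equals_full_fit(self):
        df = sim_cohort(np.random.default_rng(18), 400, beta=0.5)
        full = cox_fit(df, ["x"]).effects["x"]
        pt = hr_virtual_endpoints(df, "x", [10.0])[0]
        assert (pt.hr, pt.ci_low, pt.ci_high) == (full.hr, full.ci_low, full.ci_high)

    def test_landmark_at_zero_equals_full_fit(self):
        df = sim_cohort(np.random.default_rng(19), 400, beta=0.5)
        full = cox_fit(df, ["x"]).effects["x"]
        pt = hr_landmark(df, "x", [0.0])[0]
        assert (pt.hr, pt.ci_low, pt.ci_high) == (full.hr, full.ci_low, full.ci_high)

    def test_grid_point_before_first_event_skipped_with_reason(self):
        df = sim_cohort(np.random.default_rng(20), 200, beta=0.0, rate=0.05)
        pt = hr_virtual_endpoints(df, "x", [df["time_years"].min() / 2])[0]
        assert pt.hr is None and "events" in pt.skipped

    def test_landmark_beyond_last_event_skipped(self):
        df = sim_cohort(np.random.default_rng(21), 100, beta=0.0)
        pt = hr_landmark(df, "x", [9.999])[0]
        assert pt.skipped is not None

    def test_early_only_effect_attenuates_at_later_landmarks(self):
        rng = np.random.default_rng(22)
        n = 4000
        x = rng.binomial(1, 0.5, n).astype(float)
        r1 = 0.25 * np.exp(1.2 * x)   # strong effect in year 1 only
        t1 = rng.exponential(1 / r1)
        t = np.where(t1 < 1, t1, 1 + rng.exponential(1 / 0.1, n))
        obs = np.minimum(t, 10.0)
        df = pd.DataFrame({"x": x, "time_years": obs, "event": (t <= 10).astype(int)})
        pts = hr_landmark(df, "x", [0.0, 1.0])
        assert pts[0].hr > 1.3
        assert abs(np.log(pts[1].hr)) < abs(np.log(pts[0].hr))


class TestGroupCompare:
    def test_identical_groups_p_one_for_continuous(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 1, 2, 3],
                           "time_years": 1.0, "event": 0, "death": 0})
        p = group_compare(df, [True, True, True, False, False, False],
                          continuous=["v"], categorical=[])
        assert p["v"] == 1.0

    def test_chi_square_matches_textbook_formula(self):
        g = np.array([True] * 100 + [False] * 100)
        v = np.array([1] * 50 + [0] * 50 + [1] * 80 + [0] * 20)
        df = pd.DataFrame({"v": v, "time_years": 1.0, "event": 0})
        a, b, c, d = 50, 50, 80, 20
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        expect = stats.chi2.sf(chi2, 1)
        p = group_compare(df, g, continuous=[], categorical=["v"])
        assert p["v"] == pytest.approx(expect, rel=1e-9)

    def test_one_sd_shift_detected(self):
        rng = np.random.default_rng(23)
        v = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
        df = pd.DataFrame({"v": v, "time_years": 1.0, "event": 0})
        g = np.array([False] * 100 + [True] * 100)
        assert group_compare(df, g, continuous=["v"], categorical=[])["v"] < 0.05

    def test_empty_group_raises(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "time_years": 1.0, "event": 0})
        with pytest.raises(sv.SurvivalError):
            group_compare(df, [True, True], continuous=["v"], categorical=[])


class TestCohortRecord:
    def _kwargs(self, **over):
        base = dict(recipient_id="R1", donor_age=50, donor_sex=1,
                    recipient_age=40, recipient_sex=0, tx_year=2000, hpra=10,
                    repeat_tx=0, donation_dbd=1, cold_ischemia_h=20.0,
                    hla_mismatches=2, eplet_mismatches=10, ln_pirche=2.0,
                    step=0.5, time_years=5.0, event=0, death=0)
        base.update(over)
        return base

    def test_time_cap_enforced(self):
        with pytest.raises(ValueError):
            CohortRecord(**self._kwargs(time_years=11.0))

    def test_event_and_death_exclusive(self):
        with pytest.raises(ValueError):
            CohortRecord(**self._kwargs(event=1, death=1))
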