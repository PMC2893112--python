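"""Survival primitives against hand oracles and lifelines cross-checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylscreen import (
    auc_at_horizon,
    cox_fit,
    dichotomize_at_median,
    horizon_scan,
    km_estimate,
    logrank_test,
    td_roc,
)
from methylscreen.errors import (
    DegenerateCutpoint,
    DegenerateGroups,
    EmptyCohort,
    NoEventsByHorizon,
    NonIdentifiable,
    UndefinedSurvival,
)
from methylscreen.simulate import marker_only_params, simulate_cohort
from methylscreen.survival import cox_partial_loglik, roc_auc


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        curve = km_estimate([3.0, 5.0, 9.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_all_events_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_keeps_at_risk(self):
        # {1, 2+, 3}: S(1) = 2/3, then at t=3 one at risk -> S(3) = 0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == 0.0

    def test_empty_cohort_guard(self):
        with pytest.raises(EmptyCohort):
            km_estimate([], [])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=40))
    def test_equals_one_minus_ecdf_without_censoring(self, times):
        curve = km_estimate(times, np.ones(len(times)))
        arr = np.asarray(times)
        for t in np.unique(arr):
            ecdf = (arr <= t).mean()
            assert curve.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 4.0, 6.0, 9.0]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_hypergeometric_oracle(self):
        """A={1,2}, B={3,4}, all events: enumerate each event time by hand."""
        ta, tb = [1.0, 2.0], [3.0, 4.0]
        res = logrank_test(ta, [1, 1], tb, [1, 1])
        # t=1: n=4, nA=2, E=0.5, V=0.5*0.5*(4-1)/(4-1)... hypergeometric:
        o_minus_e, var = 0.0, 0.0
        pooled = [(1.0, True), (2.0, True), (3.0, False), (4.0, False)]
        for tj, _ in pooled:
            n_j = sum(1 for t, _ in pooled if t >= tj)
            n_aj = sum(1 for t, a in pooled if t >= tj and a)
            d_aj = 1 if (tj, True) in pooled else 0
            o_minus_e += d_aj - n_aj / n_j
            if n_j > 1:
                var += (n_aj / n_j) * (1 - n_aj / n_j)
        assert res.statistic == pytest.approx(o_minus_e ** 2 / var, abs=1e-12)

    def test_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(5, 12), rng.exponential(9, 15)
        ea, eb = rng.integers(0, 2, 12), np.ones(15)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_empty_group_guard(self):
        with pytest.raises(DegenerateGroups):
            logrank_test([], [], [1.0], [1])
        with pytest.raises(DegenerateGroups):
            logrank_test([1.0], [0], [2.0], [0])

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        tab, _ = simulate_cohort(marker_only_params(n_training=120), seed=11)
        hi = tab.locus_01 > tab.locus_01.median()
        mine = logrank_test(tab.time_months[~hi], tab.event[~hi],
                            tab.time_months[hi], tab.event[hi])
        ref = ll_logrank(tab.time_months[~hi], tab.time_months[hi],
                         tab.event[~hi], tab.event[hi])
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)


class TestDichotomize:
    def test_even_split(self):
        high, cut = dichotomize_at_median([1.0, 2.0, 3.0, 4.0])
        assert cut == 2.5
        assert list(high) == [False, False, True, True]

    def test_ties_go_to_low_group(self):
        high, cut = dichotomize_at_median([1.0, 2.0, 2.0, 5.0])
        assert cut == 2.0
        assert list(high) == [False, False, False, True]

    def test_external_cutpoint_cohort(self):
        # training-median cut applied to other scores
        high, cut = dichotomize_at_median([0.1, 0.9], cutpoint_scores=[1, 2, 3, 4])
        assert cut == 2.5
        assert list(high) == [False, False]  # both below the training median

    def test_constant_scores_guard(self):
        with pytest.raises(DegenerateCutpoint):
            dichotomize_at_median([2.0, 2.0, 2.0])


def _toy_cox_frame(rng, n=20):
    x = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    t = rng.exponential(10.0 / np.exp(0.8 * x))
    # jitter to keep times untied
    t = t + rng.random(n) * 1e-6
    return pd.DataFrame({"time_months": t, "event": np.ones(n), "x": x})


class TestCox:
    def test_beta_matches_grid_search_oracle(self, rng):
        """Single binary covariate, untied: grid-search the partial likelihood."""
        df = _toy_cox_frame(rng)
        fit = cox_fit(df, ["x"])

        t = df.time_months.to_numpy()
        x = df.x.to_numpy()
        order = np.argsort(t)
        t, x = t[order], x[order]
        grid = np.arange(-3.0, 3.0, 1e-4)

        def pl(beta):  # independent textbook form, untied & uncensored
            ll = 0.0
            for i in range(t.size):
                risk = x[i:]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
            return ll

        lls = np.array([pl(b) for b in grid[::100]])        # coarse pass
        b0 = grid[::100][np.argmax(lls)]
        fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-4)
        b_star = fine[np.argmax([pl(b) for b in fine])]
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-4)

    def test_agrees_with_lifelines_efron(self):
        from lifelines import CoxPHFitter
        tab, _ = simulate_cohort(marker_only_params(n_training=120), seed=11)
        tab["x2"] = (tab.locus_01 > 0.5).astype(float)
        fit = cox_fit(tab, ["locus_01", "x2"])
        cph = CoxPHFitter()
        cph.fit(tab[["time_months", "event", "locus_01", "x2"]],
                "time_months", "event")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_constant_covariate_guard(self):
        df = pd.DataFrame({"time_months": [1.0, 2, 3], "event": [1, 1, 1],
                           "x": [1.0, 1.0, 1.0]})
        with pytest.raises(NonIdentifiable):
            cox_fit(df, ["x"])

    def test_no_events_guard(self):
        df = pd.DataFrame({"time_months": [1.0, 2, 3], "event": [0, 0, 0],
                           "x": [1.0, 2.0, 3.0]})
        with pytest.raises(NonIdentifiable):
            cox_fit(df, ["x"])

    def test_time_rescaling_invariance(self, rng):
        df = _toy_cox_frame(rng)
        days = df.assign(time_months=df.time_months * 30.4)
        f1, f2 = cox_fit(df, ["x"]), cox_fit(days, ["x"])
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-8)

    def test_covariate_rescaling_equivariance(self, rng):
        df = _toy_cox_frame(rng)
        scaled = df.assign(x=df.x * 4.0)
        f1, f2 = cox_fit(df, ["x"]), cox_fit(scaled, ["x"])
        assert f2.beta[0] == pytest.approx(f1.beta[0] / 4.0, abs=1e-6)
        assert f2.hazard_ratio[0] == pytest.approx(f1.hazard_ratio[0] ** 0.25,
                                                   rel=1e-5)

    def test_complete_case_drops_missing(self):
        df = pd.DataFrame({"time_months": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
                           "x": [0.0, 1.0, np.nan, 1.0]})
        fit = cox_fit(df, ["x"])
        assert fit.n_used == 3

    def test_wald_ci_construction(self, rng):
        fit = cox_fit(_toy_cox_frame(rng), ["x"])
        assert fit.ci_lower[0] == pytest.approx(
            math.exp(fit.beta[0] - 1.96 * fit.se[0]))
        assert fit.ci_upper[0] == pytest.approx(
            math.exp(fit.beta[0] + 1.96 * fit.se[0]))

    def test_partial_loglik_probe_matches_fit_optimum(self, rng):
        df = _toy_cox_frame(rng)
        fit = cox_fit(df, ["x"])
        at_hat = cox_partial_loglik([fit.beta[0]], df.time_months, df.event,
                                    df[["x"]].to_numpy())
        nudged = cox_partial_loglik([fit.beta[0] + 0.01], df.time_months,
                                    df.event, df[["x"]].to_numpy())
        assert at_hat >= nudged


class TestTdROC:
    def test_equals_direct_counting_without_censoring(self, rng):
        t = rng.exponential(10, 60)
        x = rng.random(60)
        e = np.ones(60)
        horizon = float(np.median(t))
        roc = td_roc(t, e, x, horizon)
        cases = t <= horizon
        for i, c in enumerate(roc.cutpoints):
            sens_direct = np.mean(x[cases] > c)
            spec_direct = np.mean(x[~cases] <= c)
            assert roc.sensitivity[i] == pytest.approx(sens_direct, abs=1e-12)
            assert roc.specificity[i] == pytest.approx(spec_direct, abs=1e-12)

    def test_perfect_marker_has_auc_one(self, rng):
        t = np.sort(rng.exponential(10, 40))
        horizon = float((t[19] + t[20]) / 2)  # strictly between two event times
        roc = td_roc(t, np.ones(40), -t, horizon)
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_estimates_clipped_to_unit_interval(self, rng):
        tab, _ = simulate_cohort(marker_only_params(n_training=150), seed=5)
        roc = td_roc(tab.time_months, tab.event, tab.locus_01, 60.0)
        assert np.all((roc.sensitivity >= 0) & (roc.sensitivity <= 1))
        assert np.all((roc.specificity >= 0) & (roc.specificity <= 1))

    def test_nne_variant_close_to_km_on_clean_data(self, rng):
        t = rng.exponential(10, 80)
        x = rng.random(80)
        horizon = float(np.median(t))
        km = td_roc(t, np.ones(80), x, horizon, method="km")
        nne = td_roc(t, np.ones(80), x, horizon, method="nne", span=0.1)
        assert nne.auc == pytest.approx(km.auc, abs=0.1)

    def test_no_events_by_horizon_guard(self):
        with pytest.raises(NoEventsByHorizon):
            td_roc([5.0, 6.0, 7.0], [0, 0, 1], [1.0, 2.0, 3.0], 6.0)

    def test_zero_survival_guard(self):
        with pytest.raises(UndefinedSurvival):
            td_roc([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 2.0, 3.0], 3.0)


class TestAUC:
    def test_diagonal_is_half(self):
        grid = np.linspace(0, 1, 11)
        assert roc_auc(grid, grid) == pytest.approx(0.5)

    def test_through_top_left_corner_is_one(self):
        assert roc_auc([0.0, 0.0, 1.0], [0.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_staircase_matches_hand_trapezoids(self):
        fpr = np.array([0.0, 0.1, 0.3, 0.5, 0.8, 1.0])
        tpr = np.array([0.0, 0.4, 0.6, 0.7, 0.9, 1.0])
        by_hand = sum((fpr[i + 1] - fpr[i]) * (tpr[i + 1] + tpr[i]) / 2
                      for i in range(5))
        assert roc_auc(fpr, tpr) == pytest.approx(by_hand, abs=1e-12)

    def test_auc_at_horizon_is_curve_area(self, rng):
        t = rng.exponential(10, 50)
        roc = td_roc(t, np.ones(50), rng.random(50), float(np.median(t)))
        assert auc_at_horizon(roc) == pytest.approx(roc.auc)


def test_horizon_scan_reports_all_requested_horizons():
    tab, _ = simulate_cohort(marker_only_params(n_training=100), seed=3)
    scan = horizon_scan(tab.time_months, tab.event, tab.locus_01)
    assert set(scan) == {36.0, 48.0, 60.0, 80.0, 96.0}
    assert all(0 <= v <= 1 for v in scan.values() if not np.isnan(v))
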