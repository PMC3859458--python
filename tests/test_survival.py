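"""Survival engine: KM, log-rank, Cox vs hand values, oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest

from cutpointsurv import (
    DegenerateDataError,
    RankDeficiencyError,
    cox_fit,
    cox_score_test,
    coxph,
    km_estimate,
    km_median_ci,
    logrank_test,
    CoxPHRegressor,
)
from conftest import grid_max_loglik, naive_efron_loglik


def _censored_exponential(seed, n, rate=0.1, censor_rate=0.07):
    rng = np.random.default_rng(seed)
    t = rng.exponential(1 / rate, n)
    c = rng.exponential(1 / censor_rate, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestKaplanMeier:
    def test_all_censored(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(2.5) == 1.0
        assert km.median is None

    def test_hand_product_limit_no_censoring(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # censored at 1, events at 2 and 3: risk sets {3, 2} then {1}
        km = km_estimate([1, 2, 3], [0, 1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])
        assert km.survival_at(2.0) == 0.5

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 73)
        km = km_estimate(t, np.ones_like(t))
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(1.0 - np.mean(t <= tt), abs=1e-12)

    def test_greenwood_zero_where_survival_one(self):
        km = km_estimate([5, 6, 7], [0, 0, 1])
        # before the single event time survival is 1 and its variance 0
        assert km.survival_at(1.0) == 1.0
        assert km.greenwood_var[km.survival == 1.0].sum() == 0.0

    def test_median_conventions(self):
        # survival drops to exactly 0.5 at t=2: median is 2
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.median == 2.0
        # curve never reaching 0.5: undefined median
        km2 = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        assert km2.survival.min() == 0.75
        assert km2.median is None and km2.median_ci[1] is None

    def test_median_ci_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import median_survival_times

        t, e = _censored_exponential(seed=3, n=20)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = median_survival_times(kmf.confidence_interval_).to_numpy().ravel()
        assert km.median == pytest.approx(kmf.median_survival_time_, abs=1e-6)
        assert km.median_ci[0] == pytest.approx(ref[0], abs=1e-6)
        assert km.median_ci[1] == pytest.approx(ref[1], abs=1e-6)
        assert km_median_ci(km) == (km.median, km.median_ci)

    def test_curve_matches_lifelines_pointwise(self):
        from lifelines import KaplanMeierFitter

        t, e = _censored_exponential(seed=8, n=150)
        t = np.round(t, 0) + 0.5  # force ties
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(kmf.predict(tt), abs=1e-9)

    def test_export_frame(self, tmp_path):
        km = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        km.to_csv(tmp_path / "km.csv")
        back = pd.read_csv(tmp_path / "km.csv")
        assert list(back.columns) == ["time", "n_risk", "n_event", "survival", "greenwood_var"]


class TestLogRank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_hand_enumeration_four_patients(self):
        # A: events at 1, 2; B: events at 3, 4. Risk sets of size 4, 3, 2, 1.
        # E_A = 2/4 + 1/3 = 5/6 ; O_A = 2
        # V = (1/2)(1/2)(3/3) + (1/3)(2/3)(2/2) = 1/4 + 2/9 = 17/36
        # statistic = (2 - 5/6)^2 / (17/36) = 49/17
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        expected = 49 / 17
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_label_swap_symmetry(self):
        t, e = _censored_exponential(seed=5, n=40)
        g = np.arange(40) % 2
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_time_transform_invariance(self):
        t, e = _censored_exponential(seed=6, n=50)
        g = np.arange(50) % 2
        a = logrank_test(t, e, g)
        b = logrank_test(np.exp(t / 10), e, g)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import logrank_test as ll_logrank

        t, e = _censored_exponential(seed=9, n=120)
        t = np.ceil(t)  # month-granularity ties
        g = np.arange(120) % 2
        mine = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_one_group_errors(self):
        with pytest.raises(DegenerateDataError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestCox:
    def test_constant_covariate_rank_error(self):
        with pytest.raises(RankDeficiencyError, match="x0"):
            coxph(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 1, 0])

    def test_collinear_terms_named(self):
        x = np.array([0.0, 1, 0, 1, 1, 0])
        X = np.column_stack([x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            coxph(X, [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], names=["a", "b"])

    def test_six_patient_fixture_matches_grid_oracle(self, six_patient_fixture):
        f = six_patient_fixture
        fit = coxph(f["x"].reshape(-1, 1), f["time"], f["event"])
        ll_ref, beta_ref = grid_max_loglik(f["x"].reshape(-1, 1), f["time"], f["event"])
        assert fit.coef[0] == pytest.approx(beta_ref[0], abs=1e-3)
        assert fit.loglik == pytest.approx(ll_ref, abs=1e-4)

    def test_loglik_equals_enumeration_at_fitted_beta(self, six_patient_fixture):
        f = six_patient_fixture
        fit = coxph(f["x"].reshape(-1, 1), f["time"], f["event"])
        assert fit.loglik == pytest.approx(
            naive_efron_loglik(fit.coef, f["x"].reshape(-1, 1), f["time"], f["event"]), abs=1e-10
        )

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.08 * np.exp(0.5 * x1 - 0.3 * x2)))
        t = np.ceil(t)  # ties
        c = rng.exponential(30, n)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        fit = coxph(np.column_stack([x1, x2]), obs, e, names=["x1", "x2"])
        ref = CoxPHFitter().fit(pd.DataFrame({"t": obs, "e": e, "x1": x1, "x2": x2}), "t", "e")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(77)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * x)))
        c = rng.exponential(1 / 0.025, n)  # ~20% censoring
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        fit = coxph(x.reshape(-1, 1), obs, e)
        assert fit.coef[0] == pytest.approx(np.log(2), abs=0.1)

    def test_rank_invariance(self, six_patient_fixture):
        f = six_patient_fixture
        a = coxph(f["x"].reshape(-1, 1), f["time"], f["event"])
        ranks = pd.Series(f["time"]).rank(method="dense").to_numpy()
        b = coxph(f["x"].reshape(-1, 1), ranks, f["event"])
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-7)

    def test_score_test_equals_logrank(self):
        # classical identity on tie-free two-group data
        rng = np.random.default_rng(15)
        g = (np.arange(80) % 2).astype(float)
        t = rng.exponential(np.where(g > 0, 6.0, 10.0))
        e = np.ones(80, dtype=int)
        lr = logrank_test(t, e, g)
        assert cox_score_test(g, t, e) == pytest.approx(lr.statistic, abs=1e-6)

    def test_ci_brackets_hr_and_wald_p(self):
        t, e = _censored_exponential(seed=20, n=100)
        x = np.random.default_rng(20).normal(size=100)
        fit = coxph(x.reshape(-1, 1), t, e)
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]
        assert 0 <= fit.p_values[0] <= 1
        assert fit.converged

    def test_dataframe_interface(self):
        df = pd.DataFrame(
            {"os_months": [2, 3, 3, 5, 7, 9.0], "event": [1, 1, 1, 0, 1, 1], "z": [1.0, 0, 1, 0, 1, 0]}
        )
        fit = cox_fit(df, terms=["z"])
        assert fit.terms == ["z"]
        assert "z" in fit.summary().index


class TestCoxPHRegressor:
    def test_sklearn_style_fit_predict(self):
        t, e = _censored_exponential(seed=30, n=120)
        X = np.random.default_rng(30).normal(size=(120, 2))
        est = CoxPHRegressor(max_iter=30).fit(X, np.column_stack([t, e]))
        assert est.coef_.shape == (2,)
        assert est.predict(X).shape == (120,)
        assert est.get_params()["max_iter"] == 30
        cloned = CoxPHRegressor(**est.get_params())
        assert cloned.get_params() == est.get_params()

    def test_works_in_sklearn_model_selection(self):
        from sklearn.model_selection import KFold

        t, e = _censored_exponential(seed=31, n=90)
        X = np.random.default_rng(31).normal(size=(90, 2))
        y = np.column_stack([t, e])
        scores = []
        for tr, te in KFold(3, shuffle=True, random_state=0).split(X):
            est = CoxPHRegressor().fit(X[tr], y[tr])
            scores.append(est.score(X[te], y[te]))
        assert len(scores) == 3 and all(np.isfinite(scores))
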