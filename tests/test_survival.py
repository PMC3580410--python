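import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import netsig as ns


def breslow_loglik_longhand(beta, x, time, event):
    """Written-out Breslow partial log-likelihood for one covariate."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        denom = sum(np.exp(beta * x[i]) for i in risk)
        for i in deaths:
            ll += beta * x[i] - np.log(denom)
    return ll


class TestCoxFit:
    def test_matches_grid_search_oracle(self, hand_survival):
        x, time, event = hand_survival
        fit = ns.cox_fit(x, time, event)
        res = minimize_scalar(
            lambda b: -breslow_loglik_longhand(b, x, time, event),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_negating_covariate_negates_coefficient(self, hand_survival):
        x, time, event = hand_survival
        f1 = ns.cox_fit(x, time, event)
        f2 = ns.cox_fit(-x, time, event)
        assert f2.coef[0] == pytest.approx(-f1.coef[0], abs=1e-8)
        assert f2.hr[0] == pytest.approx(1 / f1.hr[0], rel=1e-8)

    def test_hr_is_exp_coef_and_ci_brackets_hr(self, hand_survival):
        x, time, event = hand_survival
        fit = ns.cox_fit(x, time, event)
        assert fit.hr[0] == np.exp(fit.coef[0])
        lo, hi = fit.ci95[0]
        assert lo < fit.hr[0] < hi

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="events"):
            ns.cox_fit(np.array([1.0, 0.0, 1.0]),
                       np.array([1.0, 2.0, 3.0]),
                       np.array([0, 0, 0]))

    def test_rank_deficient_design_is_error(self, hand_survival):
        x, time, event = hand_survival
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            ns.cox_fit(X, time, event)

    def test_separation_flagged(self):
        # covariate perfectly orders the (all-event) survival times
        time = np.arange(1.0, 9.0)
        event = np.ones(8, dtype=int)
        x = -time
        with pytest.warns(UserWarning, match="cox_fit"):
            fit = ns.cox_fit(x, time, event)
        assert not fit.converged

    def test_matches_lifelines_on_tie_free_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        n = 60
        x = rng.standard_normal(n)
        time = rng.exponential(scale=np.exp(-0.7 * x))
        event = (rng.random(n) < 0.7).astype(int)
        fit = ns.cox_fit(x, time, event)
        cph = lifelines.CoxPHFitter()
        df = pd.DataFrame({"x": x, "T": time, "E": event})
        cph.fit(df, duration_col="T", event_col="E")
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)


class TestScoreLogrankEquivalence:
    def test_score_test_equals_logrank_on_tie_free_data(self, rng):
        for _ in range(5):
            n = 40
            time = rng.permutation(np.arange(1.0, n + 1))  # distinct times
            event = (rng.random(n) < 0.7).astype(int)
            event[:2] = 1
            group = (rng.random(n) < 0.5).astype(int)
            if group.sum() in (0, n):
                continue
            chi2, _ = ns.cox_score_test(group.astype(float), time, event)
            labels = np.where(group == 1, "high", "low")
            km = ns.kaplan_meier_logrank(time, event, labels)
            assert chi2 == pytest.approx(km.logrank_chi2, abs=1e-6)


class TestKaplanMeier:
    def test_product_limit_two_events(self):
        km = ns.kaplan_meier(np.array([1.0, 2.0]), np.array([1, 1]))
        np.testing.assert_allclose(km["survival"].to_numpy(), [0.5, 0.0])

    def test_identical_groups_give_chi2_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        res = ns.kaplan_meier_logrank(time, event, group)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_hand_computed_logrank_table(self):
        # 10 subjects, two groups; O-E and V accumulated longhand below
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
        group = np.array(["A", "B", "A", "A", "B", "B", "A", "B", "A", "B"])
        o_minus_e = 0.0
        var = 0.0
        for t in time[event == 1]:
            risk = time >= t
            n = risk.sum()
            n1 = (risk & (group == "A")).sum()
            d = 1
            d1 = int(((time == t) & (event == 1) & (group == "A")).sum())
            o_minus_e += d1 - d * n1 / n
            var += (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e ** 2 / var
        res = ns.kaplan_meier_logrank(time, event, group)
        assert res.logrank_chi2 == pytest.approx(expected_chi2, abs=1e-12)

    def test_km_invariant_to_sample_order(self, rng):
        time = rng.exponential(5, 30) + 0.01
        event = (rng.random(30) < 0.6).astype(int)
        perm = rng.permutation(30)
        km1 = ns.kaplan_meier(time, event)
        km2 = ns.kaplan_meier(time[perm], event[perm])
        np.testing.assert_allclose(km1.to_numpy(), km2.to_numpy())

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            ns.kaplan_meier_logrank(np.array([1.0, 2.0]), np.array([1, 1]),
                                    np.array(["a", "a"]))


class TestMedianSplit:
    def test_even_split(self):
        labels = ns.median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = ns.median_split([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_odd_n_median_sample_low(self):
        labels = ns.median_split([1, 2, 3])
        assert list(labels) == ["low", "low", "high"]

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ns.median_split([2.0, 2.0, 2.0])
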