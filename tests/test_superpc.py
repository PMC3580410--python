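import numpy as np
import pandas as pd
import pytest

import netsig as ns
from netsig.modules import module_expression_matrix
from netsig.superpc import SuperPC, cox_univariate_score


def score_longhand(x, time, event):
    """Direct summation of U(0) and I(0) over risk sets (Breslow)."""
    U = 0.0
    I = 0.0
    for t in sorted(set(time[event == 1])):
        risk = [i for i in range(len(time)) if time[i] >= t]
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        m1 = np.mean([x[i] for i in risk])
        m2 = np.mean([x[i] ** 2 for i in risk])
        U += sum(x[i] for i in deaths) - len(deaths) * m1
        I += len(deaths) * (m2 - m1 ** 2)
    return U / np.sqrt(I)


class TestUnivariateScore:
    def test_matches_longhand_risk_set_sums(self):
        time = np.array([2.0, 4.0, 4.0, 7.0, 9.0, 12.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([0.3, -1.2, 0.7, 2.0, -0.4, 0.1])
        assert cox_univariate_score(x, time, event) == \
            pytest.approx(score_longhand(x, time, event), abs=1e-12)

    def test_sign_positive_when_larger_x_has_earlier_events(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        assert cox_univariate_score(np.array([4.0, 3.0, 2.0, 1.0]),
                                    time, event) > 0
        assert cox_univariate_score(np.array([1.0, 2.0, 3.0, 4.0]),
                                    time, event) < 0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate_score(np.ones(4), np.arange(1.0, 5.0),
                                 np.ones(4, dtype=int))


def feature_frame(rng, n_features=5, n_samples=40):
    vals = rng.standard_normal((n_features, n_samples))
    return pd.DataFrame(vals, index=[f"f{i}" for i in range(n_features)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestFit:
    def test_retain_all_equals_plain_pca(self, rng):
        frame = feature_frame(rng)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        model = SuperPC(frame, time, event)
        res = model.fit(threshold=0.0, n_components=3)
        assert res.retained == list(frame.index)
        X = frame.to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1,
                                                         keepdims=True)
        _, _, Vt = np.linalg.svd(Xs.T, full_matrices=False)
        for c in range(3):
            dot = abs(Vt[c] @ res.loadings[:, c])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self, rng):
        frame = feature_frame(rng)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        res = SuperPC(frame, time, event).fit(threshold=0.0)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(res.n_components), atol=1e-8)

    def test_single_feature_loading_is_unit(self, rng):
        frame = feature_frame(rng, n_features=1)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        res = SuperPC(frame, time, event).fit(threshold=float("-inf"))
        assert abs(res.loadings[0, 0]) == pytest.approx(1.0)

    def test_projection_reproduces_training_scores(self, rng):
        frame = feature_frame(rng)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        res = SuperPC(frame, time, event).fit(threshold=0.0)
        proj = res.predict_continuous(frame)
        np.testing.assert_allclose(proj.to_numpy(), res.train_scores,
                                   atol=1e-10)

    def test_component_summaries_report_hr_and_ci(self, rng):
        frame = feature_frame(rng)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        res = SuperPC(frame, time, event).fit(threshold=0.0, n_components=3)
        table = res.component_table()
        assert list(table.index) == ["PC1", "PC2", "PC3"]
        np.testing.assert_allclose(table["HR"], np.exp(table["coef"]))
        assert (table["CI95_low"] < table["HR"]).all()
        assert (table["HR"] < table["CI95_high"]).all()


class TestPredict:
    @pytest.fixture
    def fitted(self, rng):
        frame = feature_frame(rng)
        time = rng.exponential(5, 40) + 0.1
        event = (rng.random(40) < 0.7).astype(int)
        return frame, SuperPC(frame, time, event).fit(threshold=0.0)

    def test_training_mean_sample_scores_zero(self, fitted):
        frame, res = fitted
        mean_col = frame.mean(axis=1).to_frame("new")
        scores = res.predict_continuous(mean_col)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_one_sd_shift_moves_score_by_loading(self, fitted):
        frame, res = fitted
        base = frame.mean(axis=1)
        shifted = base.copy()
        shifted.loc[res.retained[0]] += res.scale[0]
        new = pd.DataFrame({"a": base, "b": shifted})
        scores = res.predict_continuous(new)
        diff = scores.loc["b"] - scores.loc["a"]
        np.testing.assert_allclose(diff.to_numpy(), res.loadings[0],
                                   atol=1e-10)

    def test_missing_feature_listed_in_error(self, fitted):
        frame, res = fitted
        with pytest.raises(ValueError, match="f0"):
            res.predict_continuous(frame.drop(index="f0"))

    def test_discrete_boundary_goes_low(self, fitted):
        frame, res = fitted
        mean_col = frame.mean(axis=1).to_frame("new")
        # at the training mean the score is 0; cutpoints are medians of
        # training scores, so 'low' whenever the cutpoint is >= 0
        groups = res.predict_discrete(mean_col, component=1)
        expected = "low" if res.discrete_cutpoints[0] >= 0 else "high"
        assert groups.iloc[0] == expected

    def test_discrete_training_split_sizes(self, fitted):
        frame, res = fitted
        groups = res.predict_discrete(frame, component=1)
        n = frame.shape[1]
        assert (groups == "low").sum() == int(np.ceil(n / 2))
        assert (groups == "high").sum() == n // 2

    def test_discrete_second_component_uses_pc2(self, fitted):
        frame, res = fitted
        g2 = res.predict_discrete(frame, component=2)
        scores = res.predict_continuous(frame)["PC2"]
        expected = np.where(scores > res.discrete_cutpoints[1], "high", "low")
        assert list(g2) == list(expected)

    def test_scores_invariant_to_sample_ordering(self, fitted):
        frame, res = fitted
        perm = np.random.default_rng(1).permutation(frame.shape[1])
        scrambled = frame.iloc[:, perm]
        s1 = res.predict_continuous(frame)
        s2 = res.predict_continuous(scrambled)
        np.testing.assert_allclose(s1.iloc[perm].to_numpy(), s2.to_numpy(),
                                   atol=1e-12)


class TestThresholdCV:
    def test_single_value_grid_returned(self, rng):
        frame = feature_frame(rng, n_features=4, n_samples=60)
        time = rng.exponential(5, 60) + 0.1
        event = (rng.random(60) < 0.7).astype(int)
        model = SuperPC(frame, time, event)
        theta, _ = model.select_threshold_cv(grid=[0.1], seed=0)
        assert theta == 0.1

    def test_planted_module_recovery_single_seed(self):
        cfg = ns.SyntheticConfig(seed=11)
        _, expr, truth = ns.generate(cfg)
        mods = [ns.GeneModule(genes=v, rank_id=i + 1)
                for i, v in enumerate(truth["memberships"].values())]
        M = module_expression_matrix(mods, expr)
        model = SuperPC(M, expr.time, expr.event)
        theta, cv = model.select_threshold_cv(seed=11)
        res = model.fit(theta)
        assert "M1" in res.retained  # the prognostic planted module
        corr = np.corrcoef(res.train_scores[:, 0], truth["factors"][0])[0, 1]
        assert abs(corr) > 0.9

    def test_too_few_events_rejected(self, rng):
        frame = feature_frame(rng, n_samples=20)
        time = rng.exponential(5, 20) + 0.1
        event = np.zeros(20, dtype=int)
        event[:3] = 1
        with pytest.raises(ValueError, match="fewer events"):
            SuperPC(frame, time, event).select_threshold_cv(folds=10)


def test_json_round_trip(rng):
    frame = feature_frame(rng)
    time = rng.exponential(5, 40) + 0.1
    event = (rng.random(40) < 0.7).astype(int)
    res = SuperPC(frame, time, event).fit(threshold=0.0)
    back = ns.SuperPCResults.from_json(res.to_json())
    assert back.retained == res.retained
    np.testing.assert_allclose(back.loadings, res.loadings)
    np.testing.assert_allclose(back.center, res.center)
    scores = back.predict_continuous(frame)
    np.testing.assert_allclose(scores.to_numpy(), res.train_scores, atol=1e-10)
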