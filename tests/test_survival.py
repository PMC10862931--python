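"""Feature selection, penalized Cox fitting, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatomics import (
    SimSurvSpec,
    auc_at_time,
    concordance_index,
    cox_aic,
    fit_cox_elasticnet,
    km_stratify,
    likelihood_ratio_test,
    mrmr_select,
    nri_categorical,
    simulate_survival,
)
from fatomics.estimators import CoxElasticNet, MRMRSelector, breslow_partial_loglik
from tests.conftest import harrell_c_oracle, km_oracle


def _surv(time, event):
    return pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, int)})


# ---------------------------------------------------------------------------
# mRMR


class TestMRMR:
    def _table(self, n=200, p=148, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{i:03d}" for i in range(p)])
        y = rng.integers(0, 2, n)
        return X, y

    def test_returns_exactly_k(self):
        X, y = self._table()
        assert len(mrmr_select(X, y, k=50)) == 50

    def test_duplicated_informative_feature_deferred(self):
        # a perfect copy of the first pick keeps its full relevance but has
        # redundancy 1, so in the quotient scheme its score collapses to F;
        # with a moderate signal, independent features then overtake it
        rng = np.random.default_rng(1)
        n = 400
        y = rng.integers(0, 2, n)
        signal = 0.55 * y + rng.normal(0, 1.0, n)
        X = pd.DataFrame({"sig_a": signal, "sig_b": signal.copy()})
        for i in range(20):
            X[f"noise{i:02d}"] = rng.normal(size=n)
        picked = mrmr_select(X, y, k=3)
        assert picked[0] in ("sig_a", "sig_b")
        assert picked[1] not in ("sig_a", "sig_b")
        assert picked[2] not in ("sig_a", "sig_b")

    def test_k_equals_n_features_returns_all(self):
        X, y = self._table(p=10)
        assert sorted(mrmr_select(X, y, k=10)) == sorted(X.columns)

    def test_constant_feature_excluded_with_warning(self):
        X, y = self._table(p=5)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            picked = mrmr_select(X, y, k=5)
        assert "flat" not in picked

    def test_nan_rejected(self):
        X, y = self._table(p=5)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            MRMRSelector(k=3).fit(X, y)


# ---------------------------------------------------------------------------
# Cox elastic net


class TestCoxElasticNet:
    def test_recovers_strong_true_support(self):
        beta = {f"f{i:02d}": 1.0 for i in range(5)}
        X, surv, _ = simulate_survival(SimSurvSpec(n=500, beta=beta, seed=3))
        model = fit_cox_elasticnet(X, surv, seed=0)
        assert set(beta) <= set(model.selected_features_)

    def test_null_truth_keeps_support_small(self):
        X, surv, _ = simulate_survival(SimSurvSpec(n=500, beta={}, seed=4))
        model = fit_cox_elasticnet(X, surv, seed=0)
        assert len(model.selected_features_) <= 5

    def test_lasso_drops_duplicate_column(self):
        beta = {"f00": 1.5}
        X, surv, _ = simulate_survival(SimSurvSpec(n=300, beta=beta, seed=5))
        X["f00_copy"] = X["f00"]
        model = CoxElasticNet(l1_ratio=1.0, random_state=0).fit(X, surv[["time", "event"]])
        assert (model.coef_["f00"] != 0) + (model.coef_["f00_copy"] != 0) <= 1

    def test_target_support_size(self):
        beta = {f"f{i:02d}": 0.8 for i in range(10)}
        X, surv, _ = simulate_survival(SimSurvSpec(n=400, beta=beta, seed=6))
        model = fit_cox_elasticnet(X, surv, seed=0, target_support=15)
        assert abs(len(model.selected_features_) - 15) <= 3

    def test_reproducible_given_seed(self):
        X, surv, _ = simulate_survival(SimSurvSpec(n=200, beta={"f00": 1.0}, seed=7))
        m1 = fit_cox_elasticnet(X, surv, seed=11)
        m2 = fit_cox_elasticnet(X, surv, seed=11)
        pd.testing.assert_series_equal(m1.coef_, m2.coef_)

    def test_requires_two_events(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        surv = _surv([1, 2, 3], [1, 0, 0])
        with pytest.raises(ValueError, match="events"):
            CoxElasticNet().fit(X, surv)


# ---------------------------------------------------------------------------
# concordance


class TestConcordance:
    def test_perfect_risk_ordering(self):
        time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        surv = _surv(time, np.ones(5))
        assert concordance_index(-time, surv) == 1.0

    def test_constant_risk_is_half(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.zeros(4), surv) == 0.5

    def test_hand_table_matches_bruteforce(self):
        time = [2.0, 4.0, 3.0, 5.0, 1.0, 6.0]
        event = [1, 0, 1, 1, 0, 1]
        risk = [1.2, 0.3, 0.9, -0.1, 2.0, -0.5]
        expected = harrell_c_oracle(time, event, risk)
        assert concordance_index(np.array(risk), _surv(time, event)) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_bruteforce_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        time = rng.exponential(5.0, n).round(3) + 0.001  # occasional ties
        event = rng.integers(0, 2, n)
        risk = rng.normal(size=n).round(1)  # occasional score ties
        if event.sum() == 0:
            return
        surv = _surv(time, event)
        assert concordance_index(risk, surv) == pytest.approx(
            harrell_c_oracle(time, event, risk)
        )


# ---------------------------------------------------------------------------
# AIC and partial likelihood


class TestCoxAIC:
    def test_null_model_matches_hand_computation(self):
        # Breslow null log-PL = -sum over events of log(risk-set size):
        # times 1<2<3<4<5, events at 1, 3, 4 -> -(log5 + log3 + log2)
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        event = [1, 0, 1, 1, 0]
        X = pd.DataFrame(index=range(5))
        expected_ll = -(np.log(5) + np.log(3) + np.log(2))
        assert cox_aic(X, _surv(time, event), []) == pytest.approx(-2 * expected_ll)

    def test_breslow_loglik_hand_value_with_covariate(self):
        # two subjects, both events, t1 < t2, lp = (b, 0):
        # ll = [b - log(e^b + 1)] + [0 - log(1)]
        b = 0.7
        ll = breslow_partial_loglik(np.array([b, 0.0]), np.array([1.0, 2.0]), np.array([1, 1]))
        assert ll == pytest.approx(b - np.log(np.exp(b) + 1.0))

    def test_noise_feature_increases_aic_in_expectation(self):
        diffs = []
        for seed in range(60):
            X, surv, _ = simulate_survival(
                SimSurvSpec(n=80, feature_names=("x", "z"), beta={"x": 1.0}, seed=seed)
            )
            diffs.append(cox_aic(X, surv, ["x", "z"]) - cox_aic(X, surv, ["x"]))
        assert np.mean(diffs) > 0

    def test_deterministic(self):
        X, surv, _ = simulate_survival(SimSurvSpec(n=100, beta={"f00": 1.0}, seed=8))
        assert cox_aic(X, surv, ["f00"]) == cox_aic(X, surv, ["f00"])


# ---------------------------------------------------------------------------
# time-dependent AUC


class TestAucAtTime:
    def test_perfect_ordering_no_censoring(self):
        n = 50
        time = np.linspace(0.5, 10, n)
        risk = -time  # shorter survival = higher risk
        surv = _surv(time, np.ones(n))
        assert auc_at_time(risk, surv, t=5.0) == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        X, surv, _ = simulate_survival(SimSurvSpec(n=2000, beta={}, seed=9))
        auc = auc_at_time(rng.normal(size=2000), surv, t=2.0)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_equals_binary_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        n = 300
        time = rng.exponential(3.0, n) + 1e-3
        risk = -np.log(time) + rng.normal(0, 0.5, n)
        surv = _surv(time, np.ones(n))
        t = 2.0
        expected = roc_auc_score(time <= t, risk)
        assert auc_at_time(risk, surv, t) == pytest.approx(expected, abs=1e-9)

    def test_no_events_by_horizon_rejected(self):
        surv = _surv([5.0, 6.0, 7.0], [1, 1, 1])
        with pytest.raises(ValueError, match="no events"):
            auc_at_time(np.array([1.0, 2.0, 3.0]), surv, t=1.0)


# ---------------------------------------------------------------------------
# NRI


class TestNRI:
    def test_identical_models_give_zero(self):
        X, surv, truth = simulate_survival(SimSurvSpec(n=200, beta={"f00": 1.0}, seed=11))
        risk = truth["linear_predictor"].to_numpy()
        res = nri_categorical(risk, risk, surv, t=2.0, n_bootstrap=50, seed=0)
        assert res.nri == 0.0 and res.nri_event == 0.0 and res.nri_nonevent == 0.0

    def test_informative_model_beats_noise(self):
        rng = np.random.default_rng(12)
        X, surv, truth = simulate_survival(SimSurvSpec(n=400, beta={"f00": 1.5}, seed=12))
        res = nri_categorical(
            rng.normal(size=400), truth["linear_predictor"].to_numpy(), surv,
            t=2.0, n_bootstrap=200, seed=1,
        )
        assert res.nri > 0

    def test_decomposition_identity_and_ci(self):
        rng = np.random.default_rng(13)
        X, surv, truth = simulate_survival(SimSurvSpec(n=300, beta={"f00": 1.0}, seed=13))
        res = nri_categorical(
            rng.normal(size=300), truth["linear_predictor"].to_numpy(), surv,
            t=2.0, n_bootstrap=200, seed=2,
        )
        assert res.nri == pytest.approx(res.nri_event + res.nri_nonevent, abs=1e-12)
        assert res.ci_low <= res.nri <= res.ci_high

    def test_horizon_beyond_followup_rejected(self):
        surv = _surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="beyond"):
            nri_categorical(np.r_[0.0, 1.0], np.r_[1.0, 0.0], surv, t=10.0, n_bootstrap=10)


# ---------------------------------------------------------------------------
# KM stratification and likelihood-ratio test


class TestKMStratify:
    def test_identical_strata_are_indistinguishable(self):
        rng = np.random.default_rng(14)
        time = np.tile(rng.exponential(3.0, 100), 2)
        event = np.tile(rng.integers(0, 2, 100), 2)
        risk = np.r_[np.zeros(100), np.ones(100)]  # split duplicates the cohort
        res = km_stratify(risk, _surv(time, event), split=0.5)
        assert res.logrank_p > 0.99
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.01)

    def test_km_curve_matches_hand_product_limit(self):
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 3.5]
        event = [1, 0, 1, 1, 0, 1, 1, 0]
        risk = [1, 1, 1, 1, 1, 0, 0, 0]  # first five form the high stratum
        res = km_stratify(np.array(risk), _surv(time, event), split=0.5)
        grid = [1.0, 2.0, 3.0, 4.0, 5.0]
        expected = km_oracle(time[:5], event[:5], grid)
        curve = res.curves["high"].set_index("time")["survival"]
        measured = [curve.loc[:t].iloc[-1] for t in grid]
        np.testing.assert_allclose(measured, expected)

    def test_recovers_true_group_hazard_ratio(self):
        # two groups with true HR 2.4, fixed seed
        rng = np.random.default_rng(15)
        n = 400
        group = rng.integers(0, 2, n)
        t_event = rng.exponential(1.0 / (0.3 * 2.4**group))
        t_cens = rng.uniform(0, 6.0, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        res = km_stratify(group.astype(float), _surv(np.maximum(time, 1e-9), event), split=0.5)
        assert 1.8 <= res.hazard_ratio <= 3.2

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_stratify(np.ones(4), _surv([1, 2, 3, 4], [1, 1, 0, 0]))


class TestLikelihoodRatio:
    def test_equal_models_give_p_one(self):
        X, surv, _ = simulate_survival(SimSurvSpec(n=100, beta={"f00": 1.0}, seed=16))
        res = likelihood_ratio_test(X, surv, ["f00"], ["f00"])
        assert res["delta_loglik"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == 1.0

    def test_true_predictor_is_detected(self):
        X, surv, _ = simulate_survival(
            SimSurvSpec(n=300, feature_names=("x", "z"), beta={"x": 1.5}, seed=17)
        )
        res = likelihood_ratio_test(X, surv, ["z"], ["z", "x"])
        assert res["p"] < 0.001

    def test_non_nested_refuses_chi2(self):
        X, surv, _ = simulate_survival(
            SimSurvSpec(n=100, feature_names=("x", "z", "w"), beta={"x": 1.0}, seed=18)
        )
        with pytest.warns(UserWarning, match="not nested"):
            res = likelihood_ratio_test(X, surv, ["z"], ["x", "w"])
        assert res["p"] is None and "delta_loglik" in res
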