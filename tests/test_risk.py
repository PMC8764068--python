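"""Risk-model tests: screening AUC, backward selection, CV, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoncts.risk import (BackwardLogisticRisk, _fit_logit, cv_auc,
                          cv_predictions, event_rate_threshold_metrics,
                          fit_logistic_backward, horizon_auc, univariate_auc)


class TestUnivariateAUC:
    def test_perfect_separation(self):
        assert univariate_auc([1, 2, 3, 10, 11, 12],
                              [0, 0, 0, 1, 1, 1]) == 1.0

    def test_constant_feature_is_half(self):
        assert univariate_auc(np.ones(10), [0, 1] * 5) == 0.5

    def test_hand_enumerated_pairs(self):
        # positives {1, 4} vs negatives {3, 2}: 2 of 4 concordant pairs
        assert univariate_auc([3, 1, 2, 4], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            univariate_auc([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        a = univariate_auc(scores, labels)
        b = univariate_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestLogisticFit:
    def test_matches_statsmodels_on_clean_data(self, rng):
        import statsmodels.api as sm
        X = rng.standard_normal((500, 3))
        eta = 0.5 + X @ np.array([1.0, -0.5, 0.0])
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        design = np.column_stack([np.ones(500), X])
        beta, pvals = _fit_logit(design, y)
        ref = sm.Logit(y, design).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(pvals, ref.pvalues, atol=1e-6)

    def test_separated_data_falls_back_to_ridge(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        design = np.column_stack([np.ones(40), X])
        beta, pvals = _fit_logit(design, y)
        assert np.isfinite(beta).all() and np.isfinite(pvals).all()


class TestBackwardSelection:
    def test_no_drops_when_already_small(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)),
                         columns=["a", "b", "c"])
        y = rng.integers(0, 2, 200)
        model = fit_logistic_backward(X, y, max_features=5)
        assert model.feature_ids == ["a", "b", "c"]
        assert model.selection_trace == []

    def test_informative_features_survive_selection(self, rng):
        """Two strong features among 18 noise columns are retained in at
        least 80% of replicate cohorts."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            X = pd.DataFrame(
                r.standard_normal((2000, 20)),
                columns=[f"f{j}" for j in range(20)])
            eta = -3.0 + 2.0 * X["f0"] - 2.0 * X["f1"]
            y = (r.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
            est = BackwardLogisticRisk(max_features=5).fit(X, y)
            hits += {"f0", "f1"} <= set(est.feature_ids_)
        assert hits >= 0.8 * n_rep

    def test_collinear_duplicate_dropped_without_crash(self, rng):
        v = rng.standard_normal(300)
        X = pd.DataFrame({"a": v, "dup": v.copy(),
                          "b": rng.standard_normal(300)})
        y = (v + rng.standard_normal(300) > 0).astype(int)
        est = BackwardLogisticRisk(max_features=2).fit(X, y)
        assert len(est.feature_ids_) == 2
        assert not {"a", "dup"} <= set(est.feature_ids_)

    def test_trace_records_each_drop(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 8)),
                         columns=[f"f{j}" for j in range(8)])
        y = rng.integers(0, 2, 300)
        est = BackwardLogisticRisk(max_features=5).fit(X, y)
        assert len(est.model_.selection_trace) == 3
        dropped = {name for name, _ in est.model_.selection_trace}
        assert dropped.isdisjoint(est.feature_ids_)

    def test_always_keep_covariates_never_dropped(self, rng):
        X = pd.DataFrame(rng.standard_normal((400, 8)),
                         columns=[f"f{j}" for j in range(6)] + ["bw", "ga"])
        y = rng.integers(0, 2, 400)
        est = BackwardLogisticRisk(max_features=2,
                                   always_keep=("bw", "ga")).fit(X, y)
        assert {"bw", "ga"} <= set(est.feature_ids_)
        assert len(est.feature_ids_) == 4

    @pytest.mark.parametrize("selector", ["aic", "lasso", "all_subset"])
    def test_alternative_selectors_find_the_signal(self, rng, selector):
        X = pd.DataFrame(rng.standard_normal((400, 6)),
                         columns=[f"f{j}" for j in range(6)])
        eta = 2.0 * X["f0"] - 1.0
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(int)
        est = BackwardLogisticRisk(max_features=3,
                                   selector=selector).fit(X, y)
        assert "f0" in est.feature_ids_
        assert len(est.feature_ids_) <= 3

    def test_unknown_selector_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 2)))
        with pytest.raises(ValueError, match="selector"):
            BackwardLogisticRisk(selector="magic").fit(
                X, rng.integers(0, 2, 50))

    def test_nested_demographics_never_hurt_in_sample_fit(self, rng):
        """Adding covariates cannot decrease the in-sample likelihood."""
        X = pd.DataFrame(rng.standard_normal((500, 3)),
                         columns=["a", "b", "c"])
        eta = X["a"] - 1.0
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(int)

        def loglik(est, cols):
            eta = est.decision_function(X[cols])
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        small = BackwardLogisticRisk(max_features=3).fit(X[["a"]], y)
        big = BackwardLogisticRisk(max_features=3).fit(X, y)
        assert loglik(big, list(X.columns)) >= loglik(small, ["a"]) - 1e-6


class TestCrossValidation:
    def _cohort(self, rng, n_patients=60, rows_per=5, informative=True):
        rows = []
        for p in range(n_patients):
            died = p < n_patients // 3
            for d in range(rows_per):
                x = rng.standard_normal(3)
                if informative and died:
                    x[0] += 2.0
                rows.append((f"P{p}", died, *x))
        df = pd.DataFrame(rows, columns=["pid", "died", "a", "b", "c"])
        X = df[["a", "b", "c"]]
        return X, df["died"].astype(int).to_numpy(), df["pid"].to_numpy()

    def test_informative_cohort_scores_high(self, rng):
        X, y, pids = self._cohort(rng)
        auc = cv_auc(X, y, pids, folds=5, seed=0, max_features=3)
        assert auc > 0.85

    def test_null_cohort_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y, pids = self._cohort(rng, informative=False)
            aucs.append(cv_auc(X, y, pids, folds=5, seed=seed,
                               max_features=3))
        assert 0.45 < np.mean(aucs) < 0.55

    def test_deterministic_for_fixed_seed(self, rng):
        X, y, pids = self._cohort(rng)
        a = cv_predictions(X, y, pids, folds=5, seed=3, max_features=3)
        b = cv_predictions(X, y, pids, folds=5, seed=3, max_features=3)
        np.testing.assert_array_equal(a, b)

    def test_patients_never_straddle_folds(self, rng):
        from neoncts.risk import _patient_folds
        X, y, pids = self._cohort(rng)
        assign = _patient_folds(pids, y, 5, seed=0)
        per_patient = pd.DataFrame({"p": pids, "f": assign}).groupby("p")
        assert (per_patient["f"].nunique() == 1).all()


class TestHorizonAUC:
    def test_day_one_uses_final_day_positives_only(self, rng):
        preds = rng.standard_normal(100)
        dud = np.full(100, np.nan)
        dud[:5] = 0.5                       # final-day samples
        labels = (~np.isnan(dud)).astype(int)
        preds[:5] += 3.0
        auc = horizon_auc(preds, labels, dud, 1)
        assert auc > 0.9

    def test_closer_samples_excluded(self, rng):
        preds = rng.standard_normal(50)
        dud = np.full(50, np.nan)
        dud[:10] = 3.5
        # horizons 1-3 have no positives; horizon 4 uses them
        assert np.isnan(horizon_auc(preds, np.zeros(50), dud, 1))
        assert np.isnan(horizon_auc(preds, np.zeros(50), dud, 3))
        assert not np.isnan(horizon_auc(preds, np.zeros(50), dud, 4))

    def test_effect_growing_toward_death_orders_horizons(self, rng):
        """Risk scores that strengthen near death give AUC(1d) > AUC(7d)."""
        n = 4000
        dud = np.full(n, np.nan)
        dying = rng.random(n) < 0.05
        dud[dying] = rng.uniform(0, 7, dying.sum())
        signal = np.where(dying, (7 - dud) / 7 * 2.5, 0.0)
        preds = rng.standard_normal(n) + np.nan_to_num(signal)
        labels = dying.astype(int)
        auc1 = horizon_auc(preds, labels, dud, 1)
        auc7 = horizon_auc(preds, labels, dud, 7)
        assert auc1 > auc7


class TestEventRateThreshold:
    def test_perfect_ranking(self):
        labels = np.array([0] * 95 + [1] * 5)
        preds = labels.astype(float) + np.linspace(0, 0.1, 100)
        out = event_rate_threshold_metrics(preds, labels)
        assert out["sensitivity"] == 1.0 and out["ppv"] == 1.0
        assert out["lift"] == pytest.approx(1 / 0.05)

    def test_sensitivity_equals_ppv_identity(self, rng):
        for _ in range(20):
            n = 500
            labels = (rng.random(n) < 0.05).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            preds = rng.standard_normal(n)
            out = event_rate_threshold_metrics(preds, labels)
            assert out["sensitivity"] == out["ppv"]

    def test_random_predictions_have_unit_lift(self):
        lifts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100_000
            labels = (rng.random(n) < 0.01).astype(int)
            preds = rng.standard_normal(n)
            lifts.append(event_rate_threshold_metrics(preds,
                                                      labels)["lift"])
        assert np.mean(lifts) == pytest.approx(1.0, abs=0.3)

    def test_lift_is_ppv_over_event_rate(self, rng):
        labels = (rng.random(3000) < 0.02).astype(int)
        preds = labels + rng.standard_normal(3000)
        out = event_rate_threshold_metrics(preds, labels)
        assert out["lift"] == pytest.approx(out["ppv"] / out["event_rate"])
        # worked check of the definition: sensitivity = PPV 11.1% at an
        # event rate of 0.67% corresponds to lift 0.111 / 0.0067 ~ 16.6
        assert 0.111 / 0.0067 == pytest.approx(16.57, abs=0.01)
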