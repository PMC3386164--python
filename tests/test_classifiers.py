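"""GLM hypertension classifiers: fitting, stepwise AIC, ROC, sensitivity."""

import json

import numpy as np
import pandas as pd
import pytest

from eescreen.classifiers import (
    REDUCED_SETS,
    Classifier,
    SeparationWarning,
    auc_rank,
    classifier_sensitivity,
    evaluate_split,
    fit_glm,
    roc_points,
    stepwise_aic,
    trapezoid_auc,
)
from eescreen.population import StratificationConfig


def _logistic_labels(rng, X, intercept, betas):
    lp = intercept + X @ np.asarray(betas)
    return (rng.uniform(size=len(X)) < 1 / (1 + np.exp(-lp))).astype(int)


class TestFitGlm:
    def test_null_model_intercept_is_log_odds(self):
        """Intercept-only MLE equals ln(p/(1-p)); prevalence 0.65."""
        y = np.concatenate([np.ones(6500), np.zeros(3500)])
        clf = fit_glm(pd.DataFrame(index=range(10_000)), y, label="null")
        assert clf.intercept == pytest.approx(np.log(0.65 / 0.35), abs=1e-6)
        assert clf.coef == {}

    def test_coefficient_recovery_within_wald_intervals(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(20_000, 2)), columns=["a", "b"])
        true = {"const": -2.0, "a": 1.5, "b": -0.8}
        y = _logistic_labels(rng, X.to_numpy(), true["const"], [true["a"], true["b"]])
        clf = fit_glm(X, y)
        # refit through statsmodels to extract the Wald SEs for the check
        import statsmodels.api as sm

        res = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        for name, truth in true.items():
            assert abs(res.params[name] - truth) < 1.96 * res.bse[name]
        assert clf.intercept == pytest.approx(res.params["const"], rel=1e-10)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_glm(X, np.ones(10))

    def test_perfect_separation_flagged_not_fatal(self):
        X = pd.DataFrame({"a": np.linspace(-1, 1, 200)})
        y = (X["a"] > 0).astype(int).to_numpy()
        with pytest.warns(SeparationWarning):
            clf = fit_glm(X, y)
        assert not clf.converged
        # ranking is still perfect despite the diverging coefficients
        assert auc_rank(clf.predict(X), y) == pytest.approx(1.0)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError):
            fit_glm(X, np.array([0, 1]))


class TestStepwiseAic:
    def _harness(self, seed, n=20_000, strong=(1.0, -1.0, 0.5), noise=5):
        rng = np.random.default_rng(seed)
        cols = [f"inf{i}" for i in range(len(strong))] + [f"noise{i}" for i in range(noise)]
        X = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        y = _logistic_labels(rng, X.iloc[:, : len(strong)].to_numpy(), 0.2, strong)
        return X, y

    def test_noise_predictors_dropped(self):
        X, y = self._harness(33)
        clf = stepwise_aic(X, y)
        assert set(clf.predictors) == {"inf0", "inf1", "inf2"}
        assert set(clf.meta["stepwise_dropped"]) == {f"noise{i}" for i in range(5)}

    def test_informative_predictors_survive(self):
        X, y = self._harness(32, noise=0)
        clf = stepwise_aic(X, y)
        assert set(clf.predictors) == {"inf0", "inf1", "inf2"}

    def test_aic_never_increases(self):
        X, y = self._harness(33)
        full = fit_glm(X, y)
        reduced = stepwise_aic(X, y)
        assert reduced.aic <= full.aic

    def test_single_informative_predictor(self):
        rng = np.random.default_rng(34)
        X = pd.DataFrame({"a": rng.normal(size=20_000)})
        y = _logistic_labels(rng, X.to_numpy(), 0.0, [1.2])
        clf = stepwise_aic(X, y)
        assert clf.predictors == ("a",)
        null = fit_glm(pd.DataFrame(index=range(len(y))), y)
        assert clf.aic < null.aic

    def test_insensitive_to_predictor_order(self):
        X, y = self._harness(35)
        shuffled = X[list(X.columns[::-1])]
        assert set(stepwise_aic(X, y).predictors) == set(stepwise_aic(shuffled, y).predictors)


class TestPredict:
    TABLE_COEFS = {
        "AARK": 11.9073,
        "CPR": 0.2589,
        "EARK": -5.7318,
        "GFLC": -235.5629,
        "LPPR": 18.9798,
        "NID": 2.7301,
    }

    def _clf(self):
        return Classifier(label="renal+liver", intercept=-12.6066, coef=dict(self.TABLE_COEFS))

    def test_probability_at_zero_genotype(self):
        clf = self._clf()
        p = clf.predict({k: 0.0 for k in self.TABLE_COEFS})
        assert p == pytest.approx(1 / (1 + np.exp(12.6066)), rel=1e-6)
        assert p == pytest.approx(3.34e-6, rel=5e-3)

    def test_monotone_in_coefficient_sign(self):
        clf = self._clf()
        # values chosen so the linear predictor stays far from saturation
        base = {"AARK": 1.0, "CPR": 0.3, "EARK": 0.5, "GFLC": 0.02, "LPPR": 0.1, "NID": 0.1}
        p0 = clf.predict(base)
        assert clf.predict({**base, "AARK": 1.1}) > p0  # positive coefficient
        assert clf.predict({**base, "GFLC": 0.03}) < p0  # negative coefficient

    def test_missing_predictor_named(self):
        clf = self._clf()
        with pytest.raises(KeyError, match="GFLC"):
            clf.predict({k: 0.0 for k in self.TABLE_COEFS if k != "GFLC"})

    def test_reduced_sets_match_field_definitions(self):
        assert REDUCED_SETS["renal+liver"] == ("AARK", "CPR", "EARK", "GFLC", "LPPR", "NID")
        assert REDUCED_SETS["liver"] == ("CPR", "LPPR", "NID")
        assert REDUCED_SETS["renal"] == ("AARK", "EARK", "GFLC", "NID")

    def test_json_round_trip(self, tmp_path):
        clf = self._clf()
        clf.aic = 123.4
        path = tmp_path / "clf.json"
        clf.to_json(path)
        back = Classifier.from_json(path)
        assert back.label == clf.label
        assert back.intercept == pytest.approx(clf.intercept)
        assert back.coef == pytest.approx(clf.coef)


class TestRocAuc:
    def test_perfect_and_null_scores(self):
        rng = np.random.default_rng(40)
        y = rng.integers(0, 2, size=10_000)
        assert auc_rank(y.astype(float), y) == pytest.approx(1.0)
        assert auc_rank(rng.uniform(size=10_000), y) == pytest.approx(0.5, abs=0.02)

    def test_four_point_example(self):
        """Enumerating positive/negative pairs: 3 of 4 correctly ordered."""
        assert auc_rank([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_curve_endpoints(self):
        curve = roc_points([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert 0.0 <= curve.auc <= 1.0

    def test_rank_equals_trapezoid_on_random_sets(self):
        """Tie-corrected rank AUC == trapezoidal ROC area, 500 random sets."""
        rng = np.random.default_rng(41)
        for _ in range(500):
            n = int(rng.integers(10, 60))
            scores = rng.integers(0, 8, size=n) / 7.0  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            curve = roc_points(scores, labels)
            assert abs(curve.auc - trapezoid_auc(curve)) < 1e-10

    def test_agrees_with_external_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, size=500)
        assert auc_rank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestEvaluateSplit:
    def test_map_determining_parameters_classify_well(self, campaign):
        """k_r, P_set, W_in fix the steady MAP exactly, so a held-out
        classifier on them is nearly perfect."""
        rng = np.random.default_rng(50)
        clf, roc = evaluate_split(campaign.population, ["k_r", "P_set", "W_in"], rng)
        assert roc.auc > 0.95

    def test_null_parameter_classifies_at_chance(self, campaign):
        rng = np.random.default_rng(51)
        _, roc = evaluate_split(campaign.population, ["NID_d"], rng)
        assert roc.auc == pytest.approx(0.5, abs=0.1)

    def test_unknown_train_fraction_rejected(self, campaign):
        rng = np.random.default_rng(52)
        with pytest.raises(ValueError):
            evaluate_split(campaign.population, ["k_r"], rng, train_fraction=1.0)


class TestSensitivity:
    def test_zero_coefficient_zero_variation(self):
        clf = Classifier("c", intercept=0.0, coef={"a": 0.0, "b": 1.0})
        out = classifier_sensitivity(
            clf, {"a": (0.0, 10.0), "b": (0.0, 1.0)}, {"a": 5.0, "b": 0.5}
        )
        assert out["a"] == 0.0
        assert out.index[0] == "b"  # sorted descending

    def test_saturating_single_predictor(self):
        clf = Classifier("c", intercept=0.0, coef={"a": 50.0})
        out = classifier_sensitivity(clf, {"a": (-1.0, 1.0)}, {"a": 0.0})
        assert out["a"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_sweep(self):
        """Monotone logistic: variation equals the endpoint difference of
        logistic(linear predictor), the brute-force sweep oracle."""
        clf = Classifier(
            "renal+liver",
            intercept=-12.6066,
            coef=dict(TestPredict.TABLE_COEFS),
        )
        ranges = {
            "AARK": (8.0, 24.0),
            "CPR": (0.15, 0.45),
            "EARK": (9.5, 28.5),
            "GFLC": (0.0104, 0.0312),
            "LPPR": (0.05, 0.15),
            "NID": (0.07, 0.21),
        }
        defaults = {k: (lo + hi) / 2 for k, (lo, hi) in ranges.items()}
        out = classifier_sensitivity(clf, ranges, defaults)

        def sigma(z):
            return 1 / (1 + np.exp(-z))

        for name, (lo, hi) in ranges.items():
            lp = lambda v: clf.intercept + sum(
                clf.coef[k] * (v if k == name else defaults[k]) for k in clf.coef
            )
            expected = abs(sigma(lp(hi)) - sigma(lp(lo)))
            assert out[name] == pytest.approx(expected, abs=1e-12), name
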