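"""Penalized classifier, operating point, AUC and 0.632 bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from ehrms.classifier import (ClassifierModel, auc, bootstrap632_evaluate,
                              classify_datamart, combine_632, fit_lasso_bic,
                              performance_at_threshold, predict_probability,
                              threshold_at_specificity)
from ehrms.records import ValidationError


class TestThreshold:
    def test_order_statistic_of_controls(self):
        scores = np.concatenate([np.arange(0.01, 0.201, 0.01), [0.9, 0.95]])
        labels = np.array([False] * 20 + [True] * 2)
        assert threshold_at_specificity(scores, labels, 0.95) == pytest.approx(0.19)

    def test_tied_controls(self):
        scores = np.array([0.5] * 10 + [0.9])
        labels = np.array([False] * 10 + [True])
        t = threshold_at_specificity(scores, labels, 0.95)
        assert t == 0.5
        # strict-greater rule: no control exceeds the threshold
        assert (scores[~labels] > t).sum() == 0

    def test_empirical_specificity_at_least_nominal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.random(200)
            labels = rng.random(200) < 0.4
            if labels.all() or not labels.any():
                continue
            t = threshold_at_specificity(scores, labels, 0.95)
            spec = np.mean(scores[~labels] <= t)
            assert spec >= 0.95

    def test_bad_spec_rejected(self):
        with pytest.raises(ValidationError):
            threshold_at_specificity([0.1, 0.9], [False, True], 1.0)


class TestPerformance:
    def test_confusion_table_arithmetic(self):
        # TP=9, FN=1, TN=19, FP=1
        scores = np.array([0.9] * 9 + [0.1] + [0.1] * 19 + [0.9])
        labels = np.array([True] * 10 + [False] * 20)
        p = performance_at_threshold(scores, labels, 0.5)
        assert p.sensitivity == pytest.approx(0.90)
        assert p.specificity == pytest.approx(0.95)
        assert p.ppv == pytest.approx(0.90)
        assert p.npv == pytest.approx(0.95)

    def test_threshold_above_all_scores(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([True, True, False, False])
        p = performance_at_threshold(scores, labels, 0.99)
        assert p.sensitivity == 0.0
        assert p.specificity == 1.0
        assert math.isnan(p.ppv) and "ppv" in p.undefined

    def test_perfect_separation(self):
        p = performance_at_threshold([0.9, 0.8, 0.1, 0.2],
                                     [True, True, False, False], 0.5)
        assert (p.sensitivity, p.specificity, p.ppv, p.npv) == (1, 1, 1, 1)


class TestAuc:
    def test_pairwise_example(self):
        assert auc([0.9, 0.8, 0.7, 0.85], [True, True, False, False]) == pytest.approx(0.75)

    def test_all_tied_is_half(self):
        assert auc([0.5] * 6, [True] * 3 + [False] * 3) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1], [True, True, False]) == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        s = rng.random(100)
        y = rng.random(100) < 0.5
        assert auc(s, y) == pytest.approx(auc(np.exp(5 * s), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [True, True])


class TestPredict:
    def test_null_model_gives_half(self):
        m = ClassifierModel("ALL", [], {}, 0.0, 0.1, None, 50)
        X = pd.DataFrame({"a": [1.0, 2.0]})
        assert np.allclose(predict_probability(m, X), 0.5)

    def test_intercept_log_nine(self):
        m = ClassifierModel("ALL", [], {}, math.log(9), 0.1, None, 50)
        assert predict_probability(m, pd.DataFrame({"a": [0.0]}))[0] == pytest.approx(0.9)

    def test_monotone_in_positive_coefficient(self):
        m = ClassifierModel("ALL", ["a"], {"a": 2.0}, 0.0, 0.1, None, 50)
        p = predict_probability(m, pd.DataFrame({"a": [0.0, 1.0, 2.0]}))
        assert np.all(np.diff(p) > 0)

    def test_missing_column_rejected(self):
        m = ClassifierModel("ALL", ["b"], {"b": 1.0}, 0.0, 0.1, None, 50)
        with pytest.raises(ValidationError):
            predict_probability(m, pd.DataFrame({"a": [0.0]}))


class TestLassoBic:
    def test_null_simulation_selects_almost_nothing(self):
        rng = np.random.default_rng(0)
        sparse = 0
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(500, 20)),
                             columns=[f"v{i}" for i in range(20)])
            y = rng.random(500) < 0.5
            sparse += len(fit_lasso_bic(X, y).selected_variables) <= 1
        assert sparse >= 18  # >=90% of replicate fits

    def test_soft_threshold_closed_form(self):
        """Squared-error LASSO with one standardized predictor equals the
        soft-threshold of the OLS coefficient — closed-form oracle for
        the penalized optimizer family."""
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 1.5 * x + rng.normal(size=n)
        y = y - y.mean()
        b_ols = float(x @ y / (x @ x))
        for lam in (0.1, 0.5, 1.0):
            fit = Lasso(alpha=lam, fit_intercept=False).fit(x.reshape(-1, 1), y)
            expected = np.sign(b_ols) * max(abs(b_ols) - lam * n / (x @ x), 0.0)
            assert fit.coef_[0] == pytest.approx(expected, abs=1e-6)

    def test_duplicated_column_leaves_linear_predictor_unchanged(self):
        rng = np.random.default_rng(5)
        X1 = pd.DataFrame({"a": rng.normal(size=300)})
        y = rng.random(300) < 1 / (1 + np.exp(-X1["a"]))
        X2 = pd.DataFrame({"a": X1["a"], "a2": X1["a"]})
        m1 = fit_lasso_bic(X1, y)
        m2 = fit_lasso_bic(X2, y)
        p1 = predict_probability(m1, X1)
        p2 = predict_probability(m2, X2)
        assert np.allclose(p1, p2, atol=5e-3)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        y = rng.random(200) < 0.5
        m1, m2 = fit_lasso_bic(X, y), fit_lasso_bic(X, y)
        assert m1.coefficients == m2.coefficients
        assert m1.penalty == m2.penalty

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(size=100), "c": np.ones(100)})
        y = rng.random(100) < 1 / (1 + np.exp(-2 * X["a"]))
        with pytest.warns(UserWarning, match="constant"):
            m = fit_lasso_bic(X, y)
        assert "c" not in m.selected_variables

    def test_recovers_informative_signal(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        y = rng.random(500) < 1 / (1 + np.exp(-(2 * X["a"] - 1.5 * X["b"])))
        m = fit_lasso_bic(X, y)
        assert {"a", "b"} <= set(m.selected_variables)
        assert m.coefficients["a"] > 0 > m.coefficients["b"]

    def test_too_small_or_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValidationError):
            fit_lasso_bic(X, np.array([0, 1] * 5, dtype=bool))
        X = pd.DataFrame({"a": np.arange(30.0)})
        with pytest.raises(ValidationError):
            fit_lasso_bic(X, np.ones(30, dtype=bool))


class TestBootstrap632:
    def test_closed_form_weighting(self):
        assert combine_632(0.90, 0.80) == pytest.approx(0.8368)

    def test_fixed_point(self):
        assert combine_632(0.85, 0.85) == pytest.approx(0.85)

    def test_estimate_between_apparent_and_oob(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, o = rng.random(2)
            est = combine_632(a, o)
            assert min(a, o) - 1e-12 <= est <= max(a, o) + 1e-12

    def test_estimates_and_ses_finite(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = rng.random(120) < 1 / (1 + np.exp(-2 * X["a"]))
        pe = bootstrap632_evaluate(X, y, B_cv=10, B_se=100, seed=1, n_lambda=30)
        for m in ("auc", "sensitivity", "ppv", "npv", "specificity"):
            assert min(pe.apparent[m], pe.oob_mean[m]) - 1e-12 <= pe.estimates[m] \
                   <= max(pe.apparent[m], pe.oob_mean[m]) + 1e-12
            assert pe.standard_errors[m] >= 0
        assert pe.n_bootstrap + pe.n_dropped == 10

    def test_matches_analytic_bayes_auc(self):
        """On a generator whose true log-likelihood ratio is linear in the
        counts (shared dispersion, no severity effects), the bias-corrected
        AUC agrees with the analytic Bayes AUC of the count law."""
        from ehrms.simulate import CountParams, GeneratorConfig, generate_datamart
        from ehrms.features import build_feature_matrix

        cod = {
            "ms_icd": CountParams(2.5, math.log(33 / 2.5), 0.0, 0.85),
            "mri_brain": CountParams(4.0, math.log(7.5 / 4.0), 0.0, 1.5),
        }
        cfg = GeneratorConfig(n_patients=2000, seed=21, codified=cod, narrative={})

        # oracle: AUC of the true LLR on a large fresh sample
        big = GeneratorConfig(n_patients=120000, seed=22, codified=cod, narrative={})
        sample = generate_datamart(big)
        yb = np.array([r.ms_label for r in sample])
        llr = np.zeros(len(sample))
        for name, p in cod.items():
            mu0, mu1 = p.baseline_mean, p.baseline_mean * math.exp(p.ms_log_fc)
            th = p.dispersion
            w = math.log(mu1 / (mu1 + th)) - math.log(mu0 / (mu0 + th))
            x = np.array([r.codified_counts[name] for r in sample])
            llr += w * x
        bayes = auc(llr, yb)

        cohort = generate_datamart(cfg)
        y = np.array([r.ms_label for r in cohort])
        X = build_feature_matrix(cohort, variant="COD", transform="none")
        X = X.restrict([c for c in X.catalog.names if c in cod])
        pe = bootstrap632_evaluate(X, y, B_cv=20, B_se=100, seed=2, n_lambda=50)
        assert abs(pe.estimates["auc"] - bayes) <= 0.03


class TestClassifyDatamart:
    def test_monotone_in_threshold(self):
        m = ClassifierModel("ALL", ["a"], {"a": 1.0}, 0.0, 0.1, 0.5, 50)
        X = pd.DataFrame({"a": np.linspace(-3, 3, 50)}, index=[f"P{i}" for i in range(50)])
        low = classify_datamart(m, X)["predicted_ms"].sum()
        m.threshold = 0.9
        high = classify_datamart(m, X)["predicted_ms"].sum()
        assert high <= low

    def test_threshold_above_everything_gives_empty_cohort(self):
        m = ClassifierModel("ALL", ["a"], {"a": 1.0}, 0.0, 0.1, 1.0 - 1e-12, 50)
        X = pd.DataFrame({"a": np.linspace(-3, 3, 20)}, index=[f"P{i}" for i in range(20)])
        assert classify_datamart(m, X)["predicted_ms"].sum() == 0

    def test_requires_threshold(self):
        m = ClassifierModel("ALL", ["a"], {"a": 1.0}, 0.0, 0.1, None, 50)
        with pytest.raises(ValidationError):
            classify_datamart(m, pd.DataFrame({"a": [0.0]}))


def test_model_json_round_trip(tmp_path):
    m = ClassifierModel("COD", ["a", "b"], {"a": 1.5, "b": -0.5}, 0.25, 0.01, 0.7, 300)
    m.to_json(tmp_path / "m.json", provenance="abc")
    back = ClassifierModel.from_json(tmp_path / "m.json")
    assert back == m
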