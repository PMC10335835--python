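"""Design coding, IRLS logistic fitting, analysis of deviance, predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit, logit

from ovarena import (
    DesignSpec,
    Term,
    analysis_of_deviance,
    build_design,
    fit_binomial_glm,
    fit_gaussian_lm,
    levene_test,
    predict_poff,
)

from conftest import random_binomial_instance


def spec_for(*names, response="binomial_counts", order=1, refs=None):
    refs = refs or {}
    return DesignSpec(
        response=response,
        terms=[Term(n, "categorical", refs.get(n)) for n in names],
        interaction_order=order,
    )


class TestBuildDesign:
    def test_single_factor_coding(self):
        df = pd.DataFrame({"condition": ["mock", "mock", "pred", "pred"]})
        dm = build_design(df, spec_for("condition", refs={"condition": "mock"}))
        assert dm.labels == ["Intercept", "condition[pred]"]
        np.testing.assert_array_equal(dm.X[:, 0], 1.0)
        np.testing.assert_array_equal(dm.X[:, 1], [0, 0, 1, 1])

    def test_two_factor_interaction_columns(self):
        df = pd.DataFrame(
            {"a": ["0", "1", "0", "1"], "b": ["0", "0", "1", "1"]}
        )
        dm = build_design(df, spec_for("a", "b", order=2))
        assert dm.labels == ["Intercept", "a[1]", "b[1]", "a[1]:b[1]"]
        np.testing.assert_array_equal(dm.X[:, 3], dm.X[:, 1] * dm.X[:, 2])

    def test_continuous_by_categorical(self):
        df = pd.DataFrame({"time_h": [0.0, 1, 2, 0, 1, 2],
                           "condition": ["m", "m", "m", "p", "p", "p"]})
        spec = DesignSpec(
            response="binomial_counts",
            terms=[Term("time_h", "continuous"), Term("condition", "categorical", "m")],
            interaction_order=2,
        )
        dm = build_design(df, spec)
        assert dm.labels == ["Intercept", "time_h", "condition[p]", "time_h:condition[p]"]
        np.testing.assert_array_equal(dm.X[:, 3], df["time_h"] * (df["condition"] == "p"))

    def test_aliased_columns_dropped_with_report(self):
        # duplicated factor -> the second copy is aliased with the first
        df = pd.DataFrame({"a": ["x", "y"] * 4, "b": ["x", "y"] * 4})
        with pytest.warns(UserWarning, match="aliased"):
            dm = build_design(df, spec_for("a", "b"))
        assert len(dm.dropped) == 1
        assert np.linalg.matrix_rank(dm.X) == dm.X.shape[1]

    def test_unseen_level_at_prediction_raises(self, two_condition_counts):
        dm = build_design(two_condition_counts, spec_for("condition", refs={"condition": "mock"}))
        with pytest.raises(KeyError, match="unseen level"):
            dm.row({"condition": "marsian"})


class TestBinomialFit:
    def test_intercept_only_equals_empirical_logit(self):
        counts = pd.DataFrame({"g": ["x"], "n_off": [30], "n_on": [70]})
        dm = build_design(counts, DesignSpec("binomial_counts", [Term("g")]))
        fit = fit_binomial_glm(dm, counts)
        assert fit.beta[0] == pytest.approx(logit(0.3), abs=1e-8)
        assert fit.beta[0] == pytest.approx(-0.8473, abs=1e-4)

    def test_saturated_two_group_matches_observed_proportions(self, two_condition_counts):
        dm = build_design(two_condition_counts, spec_for("condition", refs={"condition": "mock"}))
        fit = fit_binomial_glm(dm, two_condition_counts)
        pred = predict_poff(fit, [{"condition": "mock"}, {"condition": "predator"}])
        np.testing.assert_allclose(pred.p, [0.10, 0.70], atol=1e-9)

    def test_matches_derivative_free_oracle(self):
        """IRLS estimates equal direct likelihood maximization (Powell) on
        random 3-factor instances, to 1e-6 per coefficient."""
        rng = np.random.default_rng(1234)
        for _ in range(5):
            counts = random_binomial_instance(rng)
            dm = build_design(counts, spec_for("fac0", "fac1", "fac2"))
            fit = fit_binomial_glm(dm, counts)
            y = counts["n_off"].to_numpy(float)
            n = y + counts["n_on"].to_numpy(float)

            def nll(beta):
                eta = dm.X @ beta
                return -np.sum(y * eta - n * np.logaddexp(0.0, eta))

            res = optimize.minimize(
                nll, np.zeros(dm.n_coef), method="Powell",
                options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000},
            )
            np.testing.assert_allclose(fit.beta, res.x, atol=1e-6)

    def test_covariance_is_symmetric_psd(self, two_condition_counts):
        dm = build_design(two_condition_counts, spec_for("condition"))
        fit = fit_binomial_glm(dm, two_condition_counts)
        np.testing.assert_allclose(fit.cov_beta, fit.cov_beta.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov_beta) > -1e-12)

    def test_reference_level_invariance(self):
        """Swapping the reference level re-parameterizes the coefficients but
        leaves deviance and predictions unchanged."""
        rng = np.random.default_rng(9)
        counts = random_binomial_instance(rng, n_factors=2)
        for ref in ("f0l0", "f0l1"):
            spec = spec_for("fac0", "fac1", refs={"fac0": ref})
            dm = build_design(counts, spec)
            fit = fit_binomial_glm(dm, counts)
            pred = predict_poff(fit, [{"fac0": "f0l0", "fac1": "f1l0"}])
            if ref == "f0l0":
                dev0, p0 = fit.deviance, pred.p[0]
            else:
                assert fit.deviance == pytest.approx(dev0, abs=1e-8)
                assert pred.p[0] == pytest.approx(p0, abs=1e-8)

    def test_separation_detected(self):
        counts = pd.DataFrame(
            {"condition": ["a", "b"], "n_off": [0, 50], "n_on": [50, 0]}
        )
        dm = build_design(counts, spec_for("condition"))
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_binomial_glm(dm, counts, max_iter=40)
        assert fit.separated and not fit.converged

    def test_zero_trial_unit_rejected(self):
        counts = pd.DataFrame({"condition": ["a", "b"], "n_off": [0, 5], "n_on": [0, 5]})
        dm = build_design(counts, spec_for("condition"))
        with pytest.raises(ValueError, match="n_off"):
            fit_binomial_glm(dm, counts)

    def test_cross_check_against_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(77)
        counts = random_binomial_instance(rng, n_factors=2)
        dm = build_design(counts, spec_for("fac0", "fac1", order=2))
        fit = fit_binomial_glm(dm, counts)
        ref = sm.GLM(
            counts[["n_off", "n_on"]].to_numpy(float), dm.X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.deviance, ref.deviance, atol=1e-7)
        np.testing.assert_allclose(fit.cov_beta, ref.cov_params(), rtol=1e-5, atol=1e-8)


class TestGaussianFit:
    def test_exact_linear_data(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3]})
        spec = DesignSpec("gaussian", [Term("x", "continuous")])
        dm = build_design(df, spec)
        fit = fit_gaussian_lm(dm, 2.0 * df["x"])
        np.testing.assert_allclose(fit.beta, [0.0, 2.0], atol=1e-12)
        assert fit.deviance == pytest.approx(0.0, abs=1e-20)

    def test_constant_response(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        dm = build_design(df, DesignSpec("gaussian", [Term("g")]))
        fit = fit_gaussian_lm(dm, np.full(4, 3.5))
        assert fit.beta[0] == pytest.approx(3.5)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pseudo_inverse_oracle(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30)
        from ovarena.glm_core import DesignMatrix

        dm = DesignMatrix(X=X, labels=["Intercept", "a", "b", "c"],
                          spec=DesignSpec("gaussian", [Term("a", "continuous")]),
                          levels={})
        fit = fit_gaussian_lm(dm, y)
        np.testing.assert_allclose(fit.beta, np.linalg.pinv(X) @ y, atol=1e-10)

    def test_too_few_observations(self):
        df = pd.DataFrame({"x": [0.0, 1.0]})
        dm = build_design(df, DesignSpec("gaussian", [Term("x", "continuous")]))
        with pytest.raises(ValueError):
            fit_gaussian_lm(dm, np.array([1.0, 2.0]))


class TestAnalysisOfDeviance:
    def test_no_effect_gives_zero_lr(self):
        counts = pd.DataFrame(
            {"condition": ["a", "a", "b", "b"], "n_off": [5, 5, 5, 5], "n_on": [15, 15, 15, 15]}
        )
        tab = analysis_of_deviance(counts, spec_for("condition")).table
        assert tab.loc["condition", "statistic"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["condition", "p_value"] == pytest.approx(1.0, abs=1e-6)
        assert tab.loc["condition", "df"] == 1

    def test_lr_equals_loglik_gap(self, two_condition_counts):
        """For one 2-level factor on two units the term LR equals twice the
        log-likelihood gap between the saturated and intercept-only fits,
        evaluated directly from the binomial log-likelihood."""
        tab = analysis_of_deviance(two_condition_counts, spec_for("condition")).table

        def loglik(ps):
            y = np.array([10.0, 70.0])
            n = np.array([100.0, 100.0])
            return np.sum(y * np.log(ps) + (n - y) * np.log1p(-np.asarray(ps)))

        lr_direct = 2 * (loglik([0.10, 0.70]) - loglik([0.40, 0.40]))
        assert tab.loc["condition", "statistic"] == pytest.approx(lr_direct, abs=1e-6)

    def test_adding_terms_never_increases_deviance(self):
        rng = np.random.default_rng(21)
        counts = random_binomial_instance(rng, n_factors=2)
        fits = []
        for order, names in [(1, ["fac0"]), (1, ["fac0", "fac1"]), (2, ["fac0", "fac1"])]:
            dm = build_design(counts, spec_for(*names, order=order))
            fits.append(fit_binomial_glm(dm, counts))
        assert fits[0].null_deviance >= fits[0].deviance - 1e-10
        assert fits[0].deviance >= fits[1].deviance - 1e-10
        assert fits[1].deviance >= fits[2].deviance - 1e-10

    def test_type2_respects_marginality(self):
        """The test of a main effect excludes interactions containing it from
        both compared models; with an interaction present, LR(fac0) compares
        {fac1} vs {fac1, fac0}."""
        rng = np.random.default_rng(4)
        counts = random_binomial_instance(rng, n_factors=2)
        spec = spec_for("fac0", "fac1", order=2)
        tab = analysis_of_deviance(counts, spec).table
        d = {}
        for names, order in [(["fac1"], 1), (["fac0", "fac1"], 1)]:
            dm = build_design(counts, spec_for(*names, order=order))
            d[tuple(names)] = fit_binomial_glm(dm, counts).deviance
        lr_expected = d[("fac1",)] - d[("fac0", "fac1")]
        assert tab.loc["fac0", "statistic"] == pytest.approx(lr_expected, abs=1e-7)

    def test_gaussian_f_equals_squared_t(self):
        """Single 2-level factor: the F statistic equals the squared pooled
        two-sample t statistic."""
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)])
        df = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 12})
        spec = DesignSpec("gaussian", [Term("g", "categorical", "a")])
        tab = analysis_of_deviance(df, spec, response=y).table
        from scipy import stats as ss

        t, _ = ss.ttest_ind(y[10:], y[:10], equal_var=True)
        assert tab.loc["g", "statistic"] == pytest.approx(t**2, rel=1e-10)


class TestPrediction:
    def test_logit_symmetry_and_ci_shape(self, two_condition_counts):
        dm = build_design(two_condition_counts, spec_for("condition", refs={"condition": "mock"}))
        fit = fit_binomial_glm(dm, two_condition_counts)
        pred = predict_poff(fit, {"condition": "mock"})
        assert 0 < pred.ci_low[0] < pred.p[0] < pred.ci_high[0] < 1
        # back-transformed CI is asymmetric about p (p != 0.5 here)
        assert (pred.ci_high[0] - pred.p[0]) != pytest.approx(pred.p[0] - pred.ci_low[0], abs=1e-6)
        # eta = 0 -> p = 0.5 by logit symmetry
        assert expit(0.0) == 0.5


class TestLevene:
    def test_equal_spread_gives_zero_f(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        stat, p = levene_test(vals, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_f(self):
        """{0,0,10,10} vs {4,5,5,6}: absolute deviations from the group
        medians are {5,5,5,5} and {1,0,0,1}; one-way F on those is 243."""
        vals = np.array([0.0, 0, 10, 10, 4, 5, 5, 6])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        stat, _ = levene_test(vals, groups)
        assert stat == pytest.approx(243.0, rel=1e-10)

    def test_location_invariance(self):
        vals = np.array([0.0, 0, 10, 10, 4, 5, 5, 6])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        shifted = vals + np.where(groups == "a", 100.0, 0.0)
        assert levene_test(vals, groups)[0] == pytest.approx(
            levene_test(shifted, groups)[0], rel=1e-12
        )

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_test(np.ones(6), np.array(["a"] * 3 + ["b"] * 3))
        with pytest.raises(ValueError):
            levene_test(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))
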