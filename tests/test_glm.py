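import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import tolnorm as tn
from tolnorm.glm import (INTERCEPT, DegeneracyError, NestingError, Term,
                         build_design, drop_term_test, fit_irls_binomial,
                         fit_ols, gof_overdispersion, quasify)

from conftest import make_terms


def _survival_design(table, specs):
    X, y = build_design(table, make_terms(*specs), "alive_dead")
    return X, y


class TestTerm:
    def test_name_uses_canonical_order(self):
        assert Term(["BacterialLoad", "Blood", "Day"]).name == "Day:Blood:BacterialLoad"
        assert Term([]).name == "Intercept"

    def test_containment_is_strict(self):
        t3 = Term(["Day", "Blood", "BacterialLoad"])
        assert t3.contains(Term(["Day", "Blood"]))
        assert not t3.contains(t3)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            Term(["Temperature"])


class TestBuildDesign:
    def test_shape_and_intercept(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Day", "Sucrose"), "load")
        assert X.shape == (len(table), 3)
        assert (X["Intercept"] == 1).all()

    def test_interaction_is_rowwise_product(self, default_table):
        table, _ = default_table
        X, _ = _survival_design(table, ["Day", "Blood", "BacterialLoad",
                                        "Day:Blood:BacterialLoad"])
        prod = (X["Day"] * X["Blood"] * X["BacterialLoad"]).to_numpy()
        assert np.array_equal(X["Day:Blood:BacterialLoad"].to_numpy(), prod)

    def test_duplicated_term_is_degenerate(self, default_table):
        table, _ = default_table
        with pytest.raises(DegeneracyError):
            build_design(table, [Term(["Day"]), Term(["Day"])], "load")

    def test_replicate_is_never_crossed(self, default_table):
        table, _ = default_table
        with pytest.raises(ValueError, match="crossed"):
            build_design(table, [Term(["Replicate", "Day"])], "load")


class TestOls:
    def test_matches_normal_equations_oracle(self):
        # tiny bivariate set solved by explicit normal equations
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        M = np.column_stack([np.ones(4), x])
        beta_oracle = np.linalg.inv(M.T @ M) @ M.T @ y
        df = pd.DataFrame({"replicate": 1, "day": 1, "blood": 0, "sucrose": 0,
                           "alive": 1, "dead": 1, "load": x})
        X, _ = build_design(df, [Term(["BacterialLoad"])], "load")
        fit = fit_ols(X, pd.Series(y), df)
        assert np.allclose(fit.params, beta_oracle, atol=1e-10)

    def test_matches_statsmodels(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Day", "Sucrose", "Blood"), "load")
        ours = fit_ols(X, y, table.data)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(ours.params, ref.params.values, atol=1e-10)
        assert np.allclose(ours.bse, ref.bse.values, atol=1e-10)
        assert np.allclose(ours.pvalues, ref.pvalues.values, atol=1e-10)

    def test_constant_response(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Day", "Sucrose"), "load")
        fit = fit_ols(X, pd.Series(np.full(len(table), 4.2), index=y.index))
        assert fit.params[0] == pytest.approx(4.2)
        assert np.allclose(fit.params[1:], 0.0, atol=1e-12)
        assert fit.deviance == pytest.approx(0.0, abs=1e-18)

    def test_residuals_orthogonal_to_design(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Day", "Sucrose", "Blood"), "load")
        fit = fit_ols(X, y)
        resid = y.to_numpy() - fit.fittedvalues
        assert np.max(np.abs(X.to_numpy().T @ resid)) < 1e-8


class TestIrlsBinomial:
    def test_symmetric_group_gives_zero_intercept(self):
        df = pd.DataFrame({"replicate": [1], "day": [1], "blood": [0], "sucrose": [0],
                           "alive": [8], "dead": [8], "load": [0.0]})
        X, y = build_design(df, [], "alive_dead")
        fit = fit_irls_binomial(X, y, df)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_closed_form_log_odds(self):
        # saturated fit: intercept = logit(9/10), slope = logit(5/10) - logit(9/10)
        df = pd.DataFrame({"replicate": [1, 2], "day": [1, 1], "blood": [0, 1],
                           "sucrose": [0, 0], "alive": [9, 5], "dead": [1, 5],
                           "load": [0.0, 0.0]})
        X, y = build_design(df, [Term(["Blood"])], "alive_dead")
        fit = fit_irls_binomial(X, y, df)
        assert fit.params[0] == pytest.approx(np.log(9.0), abs=1e-10)
        assert fit.params[1] == pytest.approx(-np.log(9.0), abs=1e-10)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_glm(self, default_table):
        table, _ = default_table
        X, y = _survival_design(table, ["Day", "Blood", "BacterialLoad",
                                        "Day:Blood", "Day:BacterialLoad",
                                        "Blood:BacterialLoad",
                                        "Day:Blood:BacterialLoad"])
        ours = fit_irls_binomial(X, y, table.data)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.params, ref.params.values, atol=1e-8)
        assert np.allclose(ours.bse, ref.bse.values, atol=1e-7)
        assert ours.deviance == pytest.approx(ref.deviance, abs=1e-8)
        assert ours.pearson_chi2 == pytest.approx(ref.pearson_chi2, abs=1e-8)

    def test_fitted_proportions_strictly_inside_unit_interval(self, default_table):
        table, _ = default_table
        X, y = _survival_design(table, ["Day", "Blood", "BacterialLoad"])
        fit = fit_irls_binomial(X, y, table.data)
        assert np.all(fit.fittedvalues > 0) and np.all(fit.fittedvalues < 1)
        assert fit.deviance >= 0


class TestOverdispersion:
    def test_gof_pvalues_and_phi(self, default_table):
        table, _ = default_table
        X, y = _survival_design(table, ["Day", "Blood", "BacterialLoad"])
        fit = fit_irls_binomial(X, y, table.data)
        gof = gof_overdispersion(fit)
        assert gof["phi"] == pytest.approx(fit.pearson_chi2 / fit.df_resid)
        assert 0 <= gof["deviance_p"] <= 1 and 0 <= gof["pearson_p"] <= 1

    def test_saturated_model_undefined(self):
        df = pd.DataFrame({"replicate": [1, 2], "day": [1, 1], "blood": [0, 1],
                           "sucrose": [0, 0], "alive": [9, 5], "dead": [1, 5],
                           "load": [0.0, 0.0]})
        X, y = build_design(df, [Term(["Blood"])], "alive_dead")
        fit = fit_irls_binomial(X, y, df)
        with pytest.raises(ValueError, match="[Ss]aturated"):
            gof_overdispersion(fit)

    def test_quasify_scales_ses_exactly(self, default_table):
        table, _ = default_table
        X, y = _survival_design(table, ["Day", "Blood", "BacterialLoad"])
        fit = fit_irls_binomial(X, y, table.data)
        q4 = quasify(fit, phi=4.0)
        assert np.array_equal(q4.params, fit.params)
        assert np.allclose(q4.bse, 2.0 * fit.bse, rtol=0, atol=0)
        assert q4.family == "quasibinomial" and q4.statistic_kind == "t"
        q1 = quasify(fit, phi=1.0)
        assert np.array_equal(q1.cov, fit.cov)


class TestDropTermTest:
    def test_identical_models_give_p_one(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Day"), "load")
        fit = fit_ols(X, y)
        assert drop_term_test(fit, fit) == 1.0

    def test_gaussian_single_drop_equals_t_test(self, default_table):
        # F(1, df) on one dropped column reproduces the two-sided t p-value
        table, _ = default_table
        Xf, y = build_design(table, make_terms("Day", "Sucrose"), "load")
        Xr, _ = build_design(table, make_terms("Day"), "load")
        full, red = fit_ols(Xf, y), fit_ols(Xr, y)
        idx = full.names.index("Sucrose")
        assert drop_term_test(full, red) == pytest.approx(full.pvalues[idx], abs=1e-10)

    def test_perfect_predictor_drop_is_extreme(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"replicate": 1, "day": 1, "blood": 0, "sucrose": 0,
                           "alive": 1, "dead": 1,
                           "load": np.linspace(0, 5, 30)})
        y = pd.Series(3.0 * df["load"] + rng.normal(0, 1e-6, 30))
        Xf, _ = build_design(df, [Term(["BacterialLoad"])], "load")
        Xr, _ = build_design(df, [], "load")
        assert drop_term_test(fit_ols(Xf, y), fit_ols(Xr, y)) < 1e-6

    def test_non_nested_rejected(self, default_table):
        table, _ = default_table
        Xa, y = build_design(table, make_terms("Day"), "load")
        Xb, _ = build_design(table, make_terms("Sucrose"), "load")
        with pytest.raises(NestingError):
            drop_term_test(fit_ols(Xa, y), fit_ols(Xb, y))

    def test_binomial_lr_matches_statsmodels_deviance_difference(self, default_table):
        from scipy import stats
        table, _ = default_table
        Xf, y = _survival_design(table, ["Day", "BacterialLoad"])
        Xr, _ = _survival_design(table, ["Day"])
        full = fit_irls_binomial(Xf, y, table.data)
        red = fit_irls_binomial(Xr, y, table.data)
        p = drop_term_test(full, red)
        assert p == pytest.approx(stats.chi2.sf(red.deviance - full.deviance, 1), abs=1e-12)
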