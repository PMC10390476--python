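import numpy as np
import pandas as pd
import pytest

import tolnorm as tn
from tolnorm.glm import FitResult, Term, build_design, fit_irls_binomial
from tolnorm.marginal import (build_trajectory, emm_curve, marginal_slope,
                              reference_grid, trajectory_frame)

from conftest import make_terms

BLOOD_LOAD_TERMS = make_terms("Blood", "BacterialLoad", "Blood:BacterialLoad")


def fixed_coef_fit(coef: dict, load_range=(0.0, 10.0), n=21) -> FitResult:
    """A survival fit object with prescribed coefficients over blood x load.

    The data frame only supplies the grid ranges; covariance is a small
    diagonal so SEs are well-defined.
    """
    blood = np.repeat([0, 1], n)
    load = np.tile(np.linspace(*load_range, n), 2)
    df = pd.DataFrame({"replicate": 1, "day": 1, "blood": blood, "sucrose": 0,
                       "alive": 10, "dead": 5, "load": load})
    X = build_design(df, BLOOD_LOAD_TERMS, None)
    names = list(X.columns)
    params = np.array([coef[name] for name in names])
    return FitResult(
        names=names, terms=X.attrs["terms"], params=params,
        cov=np.eye(len(names)) * 1e-4, df_resid=len(df) - len(names),
        nobs=len(df), family="binomial", link="logit", deviance=0.0,
        pearson_chi2=0.0, dispersion=1.0, statistic_kind="z", X=X,
        y=df[["alive", "dead"]], data=df, fittedvalues=np.full(len(df), 0.5))


# published day-1 survival model coefficients for the fixture
DAY1_COEF = {"Intercept": 0.93, "Blood": 1.20, "BacterialLoad": 0.08,
             "Blood:BacterialLoad": -0.17}


class TestEmmCurve:
    def test_intercept_only_flat_at_half(self):
        fit = fixed_coef_fit({"Intercept": 0.0, "Blood": 0.0, "BacterialLoad": 0.0,
                              "Blood:BacterialLoad": 0.0})
        curve = emm_curve(fit, by=None)
        assert np.allclose(curve["prediction"], 0.5)

    def test_response_scale_bounded(self, default_table):
        table, _ = default_table
        sub = tn.subset(table, day=1)
        X, y = build_design(sub, BLOOD_LOAD_TERMS, "alive_dead")
        fit = fit_irls_binomial(X, y, sub.data)
        curve = emm_curve(fit, by="Blood", scale="response")
        assert ((curve["prediction"] > 0) & (curve["prediction"] < 1)).all()
        assert set(curve["level"]) == {0, 1}

    def test_curves_cross_where_blood_effect_cancels(self):
        # blood and no-blood predictions meet at load = -beta_blood / beta_int
        fit = fixed_coef_fit(DAY1_COEF)
        crossing = -DAY1_COEF["Blood"] / DAY1_COEF["Blood:BacterialLoad"]
        assert crossing == pytest.approx(7.0588, abs=1e-3)
        curve = emm_curve(fit, by="Blood", scale="linear", n_points=200)
        diff = (curve[curve["level"] == 1]["prediction"].to_numpy()
                - curve[curve["level"] == 0]["prediction"].to_numpy())
        x = curve[curve["level"] == 0]["x"].to_numpy()
        sign_change = x[np.where(np.diff(np.sign(diff)))[0]]
        assert len(sign_change) == 1
        assert sign_change[0] == pytest.approx(crossing, abs=0.1)

    def test_linear_monotone_in_eta(self):
        fit = fixed_coef_fit({"Intercept": 0.0, "Blood": 0.0, "BacterialLoad": 0.5,
                              "Blood:BacterialLoad": 0.0})
        curve = emm_curve(fit, by=None, scale="response")
        assert (np.diff(curve["prediction"]) > 0).all()

    def test_absent_factor_rejected(self):
        fit = fixed_coef_fit(DAY1_COEF)
        with pytest.raises(ValueError, match="Sucrose"):
            emm_curve(fit, by="Sucrose")


class TestMarginalSlope:
    def test_published_coefficient_fixture_slopes(self):
        # slope per blood level is beta_load + blood * beta_interaction
        fit = fixed_coef_fit(DAY1_COEF)
        sl = marginal_slope(fit, by="Blood").set_index("level")
        assert sl.loc[0, "slope"] == pytest.approx(0.08, abs=1e-10)
        assert sl.loc[1, "slope"] == pytest.approx(0.08 - 0.17, abs=1e-10)

    def test_difference_quotient_exact_for_any_h(self):
        fit = fixed_coef_fit(DAY1_COEF)
        for h in (1e-6, 1e-3, 0.5, 2.0):
            sl = marginal_slope(fit, by="Blood", h=h).set_index("level")
            assert sl.loc[1, "slope"] == pytest.approx(-0.09, abs=1e-10)

    def test_se_invariant_to_grid_density(self, default_table):
        table, _ = default_table
        sub = tn.subset(table, day=1)
        X, y = build_design(sub, BLOOD_LOAD_TERMS, "alive_dead")
        fit = fit_irls_binomial(X, y, sub.data)
        a = marginal_slope(fit, by="Blood", n_points=10)
        b = marginal_slope(fit, by="Blood", n_points=50)
        assert np.allclose(a["slope"], b["slope"], atol=1e-10)
        assert np.allclose(a["se"], b["se"], atol=1e-10)

    def test_slope_contrast_equals_interaction_coefficient(self, default_table):
        table, _ = default_table
        sub = tn.subset(table, day=5)
        X, y = build_design(sub, BLOOD_LOAD_TERMS, "alive_dead")
        fit = fit_irls_binomial(X, y, sub.data)
        sl = marginal_slope(fit, by="Blood").set_index("level")
        contrast = sl.loc[1, "slope"] - sl.loc[0, "slope"]
        assert contrast == pytest.approx(
            fit.coef["Blood:BacterialLoad"], abs=1e-10)

    def test_no_interaction_gives_identical_slopes(self, default_table):
        table, _ = default_table
        X, y = build_design(table, make_terms("Blood", "BacterialLoad"), "alive_dead")
        fit = fit_irls_binomial(X, y, table.data)
        sl = marginal_slope(fit, by="Blood")
        assert sl["slope"].nunique() == 1
        assert sl["slope"].iloc[0] == pytest.approx(fit.coef["BacterialLoad"], abs=1e-10)

    def test_nonpositive_h_rejected(self):
        fit = fixed_coef_fit(DAY1_COEF)
        with pytest.raises(ValueError):
            marginal_slope(fit, by="Blood", h=0.0)


class TestTrajectory:
    @staticmethod
    def _slopes():
        return pd.DataFrame([
            {"blood": b, "day": d, "slope": 0.1 * b - 0.02 * d, "se": 0.05}
            for b in (0, 1) for d in (1, 3, 5)])

    def test_two_groups_three_days_six_points(self, default_table):
        table, _ = default_table
        points = build_trajectory(table, self._slopes())
        assert len(points) == 6
        frame = trajectory_frame(points)
        assert set(zip(frame["blood"], frame["day"])) == \
            {(b, d) for b in (0, 1) for d in (1, 3, 5)}
        assert (frame["load_q1"] <= frame["load_median"]).all()
        assert (frame["load_median"] <= frame["load_q3"]).all()

    def test_constant_load_constant_resistance_coordinate(self):
        df = pd.DataFrame([
            {"replicate": r, "day": d, "blood": b, "sucrose": 0,
             "alive": 10, "dead": 2, "load": 3.0}
            for r in (1, 2) for b in (0, 1) for d in (1, 3, 5)])
        frame = trajectory_frame(build_trajectory(df, self._slopes()))
        assert (frame["load_median"] == 3.0).all()
        assert (frame["load_q3"] - frame["load_q1"] == 0).all()

    def test_missing_day_flagged(self, default_table):
        table, _ = default_table
        slopes = self._slopes().query("day != 3")
        with pytest.warns(UserWarning, match="trajectory gap"):
            points = build_trajectory(table, slopes)
        assert len(points) == 4


def test_reference_grid_covers_levels_and_range(default_table):
    table, _ = default_table
    sub = tn.subset(table, day=1)
    X, y = build_design(sub, BLOOD_LOAD_TERMS, "alive_dead")
    fit = fit_irls_binomial(X, y, sub.data)
    grid = reference_grid(fit, n_points=7)
    assert set(grid["blood"]) == {0, 1}
    assert grid["load"].min() == sub.data["load"].min()
    assert grid["load"].max() == sub.data["load"].max()
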