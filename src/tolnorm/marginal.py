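"""Estimated marginal means, marginal load-slopes, and defense trajectories.

Tolerance is read off a fitted survival model as the slope of the linear
predictor (log-odds of survival) with respect to bacterial load, separately
for each level of a grouping factor. The slope is computed as a central
difference quotient of predictions over a reference grid — the numerical
analogue of an `emtrends` call — with a delta-method standard error from
the coefficient covariance. For models linear in load the quotient is
exact: it collapses to the coefficient combination ``beta_load +
beta_interaction * level`` independent of the step size or grid density.

The resistance-tolerance trajectory pairs, per group and day, the group's
median pooled load (with interquartile range; resistance is inversely
related to load) with its marginal survival-on-load slope (with SE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm import VARIABLE_COLUMNS, FitResult, build_design

__all__ = ["reference_grid", "emm_curve", "marginal_slope", "TrajectoryPoint",
           "build_trajectory", "trajectory_frame"]

DEFAULT_GRID_POINTS = 25


def _fit_variables(fit: FitResult) -> set[str]:
    return set().union(*(t.factors for t in fit.terms)) if fit.terms else set()


def _require(fit: FitResult, var: str) -> None:
    if var not in _fit_variables(fit):
        raise ValueError(f"variable {var!r} does not appear in the fitted model")


def reference_grid(fit: FitResult, over: str = "BacterialLoad",
                   by: str | None = "Blood",
                   n_points: int = DEFAULT_GRID_POINTS) -> pd.DataFrame:
    """Factor levels x evenly spaced covariate values over the observed range.

    Variables in the fit other than ``over`` and ``by`` are held at their
    observed mean (for the binary treatment codes this averages predictions
    over the observed group composition).
    """
    _require(fit, over)
    over_col = VARIABLE_COLUMNS[over]
    values = fit.data[over_col].to_numpy(dtype=float)
    xs = np.linspace(values.min(), values.max(), n_points)
    levels = [None]
    if by is not None:
        _require(fit, by)
        levels = sorted(fit.data[VARIABLE_COLUMNS[by]].unique())
    base = {VARIABLE_COLUMNS[v]: float(fit.data[VARIABLE_COLUMNS[v]].mean())
            for v in _fit_variables(fit) if v not in (over, by)}
    rows = []
    for lev in levels:
        for x in xs:
            row = dict(base)
            row[over_col] = float(x)
            if by is not None:
                row[VARIABLE_COLUMNS[by]] = lev
            rows.append(row)
    return pd.DataFrame(rows)


def emm_curve(fit: FitResult, over: str = "BacterialLoad", by: str | None = "Blood",
              scale: str = "response", n_points: int = DEFAULT_GRID_POINTS) -> pd.DataFrame:
    """Predicted survival (or linear predictor) over the load range per level.

    Response-scale predictions pass through the inverse logit; their SEs
    follow by the delta method, ``SE_response = SE_linear * mu (1 - mu)``.
    Gaussian fits are returned on the linear scale regardless of ``scale``.
    """
    if scale not in ("response", "linear"):
        raise ValueError("scale must be 'response' or 'linear'")
    grid = reference_grid(fit, over=over, by=by, n_points=n_points)
    X = build_design(grid, fit.terms)
    eta, se = fit.predict_linear(X)
    out = grid.copy()
    out["x"] = grid[VARIABLE_COLUMNS[over]]
    if by is not None:
        out["level"] = grid[VARIABLE_COLUMNS[by]]
    if scale == "response" and fit.link == "logit":
        mu = expit(eta)
        out["prediction"] = mu
        out["se"] = se * mu * (1 - mu)
    else:
        out["prediction"] = eta
        out["se"] = se
    keep = (["level"] if by is not None else []) + ["x", "prediction", "se"]
    return out[keep]


def marginal_slope(fit: FitResult, wrt: str = "BacterialLoad",
                   by: str | None = "Blood", h: float | None = None,
                   n_points: int = DEFAULT_GRID_POINTS) -> pd.DataFrame:
    """Marginal slope of the linear predictor w.r.t. a covariate, per level.

    Central difference quotient ``(eta(x+h) - eta(x-h)) / 2h`` averaged over
    the reference grid; SE by the delta method on the averaged gradient.
    ``h`` defaults to 1/1000 of the observed covariate range.
    """
    _require(fit, wrt)
    col = VARIABLE_COLUMNS[wrt]
    values = fit.data[col].to_numpy(dtype=float)
    rng = float(values.max() - values.min())
    if h is None:
        h = rng / 1000.0 if rng > 0 else 1e-3
    if h <= 0:
        raise ValueError(f"step h must be positive, got {h}")
    grid = reference_grid(fit, over=wrt, by=by, n_points=n_points)
    levels = sorted(grid[VARIABLE_COLUMNS[by]].unique()) if by is not None else [None]
    rows = []
    for lev in levels:
        g = grid if lev is None else grid[grid[VARIABLE_COLUMNS[by]] == lev]
        up, down = g.copy(), g.copy()
        up[col] = g[col] + h
        down[col] = g[col] - h
        Xu = build_design(up, fit.terms)[fit.names].to_numpy(dtype=float)
        Xd = build_design(down, fit.terms)[fit.names].to_numpy(dtype=float)
        grad = ((Xu - Xd) / (2.0 * h)).mean(axis=0)
        slope = float(grad @ fit.params)
        se = float(np.sqrt(grad @ fit.cov @ grad))
        row = {"slope": slope, "se": se}
        if by is not None:
            row["level"] = lev
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrajectoryPoint:
    """One group x day point on the resistance-tolerance plane.

    Resistance is summarized by the median pooled load (interquartile range
    attached; note the conventional reversed axis — lower load means higher
    resistance). Tolerance is the marginal survival-on-load slope with its
    standard error, on the linear-predictor (logit) scale.
    """

    blood: int
    day: int
    load_median: float
    load_q1: float
    load_q3: float
    slope: float
    slope_se: float


def build_trajectory(table, slopes: pd.DataFrame) -> list[TrajectoryPoint]:
    """Pair per-group-per-day load medians with marginal tolerance slopes.

    ``slopes`` is tidy with columns ``blood, day, slope, se`` (one row per
    group x day, e.g. from day-specific survival fits). Days present in the
    table but missing a slope (or vice versa) are flagged with a warning
    and skipped.
    """
    df = getattr(table, "data", table)
    have_data = {(int(b), int(d)) for b, d in df[["blood", "day"]].itertuples(index=False)}
    have_slopes = {(int(r.blood), int(r.day)) for r in slopes.itertuples(index=False)}
    for missing in sorted(have_data - have_slopes):
        warnings.warn(f"no tolerance slope for group blood={missing[0]}, "
                      f"day={missing[1]}; trajectory gap", stacklevel=2)
    for missing in sorted(have_slopes - have_data):
        warnings.warn(f"no load observations for group blood={missing[0]}, "
                      f"day={missing[1]}; trajectory gap", stacklevel=2)
    points = []
    for row in slopes.sort_values(["blood", "day"]).itertuples(index=False):
        key = (int(row.blood), int(row.day))
        if key not in have_data:
            continue
        loads = df.loc[(df["blood"] == key[0]) & (df["day"] == key[1]), "load"]
        q1, med, q3 = np.quantile(loads.to_numpy(dtype=float), [0.25, 0.5, 0.75])
        points.append(TrajectoryPoint(
            blood=key[0], day=key[1], load_median=float(med),
            load_q1=float(q1), load_q3=float(q3),
            slope=float(row.slope), slope_se=float(row.se)))
    return points


def trajectory_frame(points: list[TrajectoryPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])
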