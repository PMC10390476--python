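"""Linear and (quasi)binomial model fitting for grouped infection data.

Two families cover the analysis: Gaussian identity-link models for pooled
bacterial load ("resistance" models) and binomial logit models for grouped
cage survival ("tolerance" models). Grouped binomial counts are frequently
overdispersed — the realised variance exceeds ``n p (1-p)`` — so binomial
fits carry their residual deviance and Pearson chi-square, both compared to
a chi-square on the residual degrees of freedom as goodness-of-fit tests.
When either test rejects, inference is corrected quasi-style: the variance
is ``phi * mu(1-mu)`` with ``phi`` estimated as Pearson X^2 / df_resid,
standard errors inflate by ``sqrt(phi)``, and Wald statistics switch from z
to t on the residual degrees of freedom. Point estimates never change.

Model terms are sets of variable names; an interaction column is the
row-wise product of its main-effect columns (all treatment codings here are
binary or numeric, so no factor expansion is needed except for the
replicate blocking factor, which enters as dummy columns and is never
crossed with other variables).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from functools import total_ordering
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VARIABLE_COLUMNS",
    "Term",
    "INTERCEPT",
    "DegeneracyError",
    "ConvergenceError",
    "NestingError",
    "SeparationWarning",
    "FitResult",
    "build_design",
    "fit_ols",
    "fit_irls_binomial",
    "gof_overdispersion",
    "quasify",
    "drop_term_test",
]

#: model variable name -> experiment-table column
VARIABLE_COLUMNS = {
    "Day": "day",
    "Blood": "blood",
    "Sucrose": "sucrose",
    "BacterialLoad": "load",
    "Replicate": "replicate",
}

_VAR_ORDER = {v: i for i, v in enumerate(VARIABLE_COLUMNS)}


class DegeneracyError(ValueError):
    """Design matrix is rank deficient (aliased columns)."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class NestingError(ValueError):
    """Models passed to a drop test are not nested."""


class SeparationWarning(UserWarning):
    """(Quasi-)complete separation detected; coefficients unreliable."""


@total_ordering
@dataclass(frozen=True)
class Term:
    """A model term: a set of variable names; |factors| is its order.

    The empty set is the intercept. Terms sort by order then by canonical
    variable order, which fixes the deterministic tie-break used in
    backward elimination.
    """

    factors: frozenset[str]

    def __init__(self, factors=()):
        object.__setattr__(self, "factors", frozenset(factors))
        unknown = self.factors - set(VARIABLE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown model variable(s): {sorted(unknown)}")

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def name(self) -> str:
        if not self.factors:
            return "Intercept"
        return ":".join(sorted(self.factors, key=_VAR_ORDER.__getitem__))

    def contains(self, other: "Term") -> bool:
        """True if ``other`` is marginal to (contained in) this term."""
        return other.factors < self.factors

    def _key(self):
        return (self.order, tuple(sorted(_VAR_ORDER[f] for f in self.factors)))

    def __lt__(self, other: "Term") -> bool:
        return self._key() < other._key()

    def __repr__(self) -> str:
        return f"Term({self.name})"


INTERCEPT = Term(())


def _term_columns(df: pd.DataFrame, term: Term) -> pd.DataFrame:
    """Design columns for one term (product of main-effect columns)."""
    if term == INTERCEPT:
        return pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    if "Replicate" in term.factors:
        if term.order > 1:
            raise ValueError("the replicate blocking factor is never crossed "
                             "with other variables")
        levels = sorted(df["replicate"].unique())
        cols = {f"Replicate[{lev}]": (df["replicate"] == lev).astype(float)
                for lev in levels[1:]}
        return pd.DataFrame(cols, index=df.index)
    col = np.ones(len(df))
    for factor in term.factors:
        col = col * df[VARIABLE_COLUMNS[factor]].to_numpy(dtype=float)
    return pd.DataFrame({term.name: col}, index=df.index)


def build_design(data, terms, response: str | None = None):
    """Assemble the design matrix and response for a term list.

    Parameters
    ----------
    data:
        :class:`~tolnorm.dataset.ExperimentTable` or its dataframe.
    terms:
        Model terms (the intercept is added if absent).
    response:
        ``"load"`` for the Gaussian load response, ``"alive_dead"`` for
        the grouped binomial survival response, or ``None`` for a
        prediction-only design matrix (returns X alone).

    Returns
    -------
    (X, y) where X is a DataFrame with one named column per coefficient and
    y is a Series (load) or an (alive, dead) count DataFrame.
    """
    df = getattr(data, "data", data)
    terms = list(terms)
    if INTERCEPT not in terms:
        terms = [INTERCEPT] + terms
    if len(set(terms)) != len(terms):
        dupes = sorted({t.name for t in terms if terms.count(t) > 1})
        raise DegeneracyError(f"duplicated term(s): {dupes}")
    terms = sorted(set(terms))
    for term in terms:
        for factor in term.factors:
            if VARIABLE_COLUMNS[factor] not in df.columns:
                raise ValueError(f"variable {factor!r} not present in table")
    X = pd.concat([_term_columns(df, t) for t in terms], axis=1)
    X.attrs["terms"] = terms
    if response is None:
        # prediction grids hold factors fixed, so constant (collinear)
        # columns are expected; the rank check applies to estimation only
        return X
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise DegeneracyError(f"rank-deficient design; aliased columns: {aliased}",
                              aliased=aliased)
    if response == "load":
        return X, df["load"].astype(float)
    if response == "alive_dead":
        return X, df[["alive", "dead"]].astype(float)
    raise ValueError(f"unknown response {response!r}")


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy pass naming columns linearly dependent on earlier ones."""
    aliased, kept = [], []
    for j, name in enumerate(names):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            aliased.append(name)
        else:
            kept.append(j)
    return aliased


@dataclass
class FitResult:
    """A fitted model with everything needed for inference and prediction."""

    names: list[str]
    terms: list[Term]
    params: np.ndarray
    cov: np.ndarray
    df_resid: int
    nobs: int
    family: str            # gaussian | binomial | quasibinomial
    link: str              # identity | logit
    deviance: float
    pearson_chi2: float
    dispersion: float      # sigma^2 (gaussian) or phi (binomial families)
    statistic_kind: str    # "t" or "z"
    X: pd.DataFrame
    y: pd.DataFrame | pd.Series
    data: pd.DataFrame
    fittedvalues: np.ndarray
    weights: np.ndarray | None = None   # binomial totals per row
    converged: bool = True
    separation: bool = False
    n_iter: int = 0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def statistic(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        stat = self.statistic
        if self.statistic_kind == "z":
            return 2.0 * stats.norm.sf(np.abs(stat))
        return 2.0 * stats.t.sf(np.abs(stat), self.df_resid)

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.params, index=self.names)

    def term_slice(self, term: Term) -> list[int]:
        """Column indices belonging to a term (replicate spans several)."""
        if "Replicate" in term.factors:
            return [i for i, n in enumerate(self.names) if n.startswith("Replicate[")]
        return [i for i, n in enumerate(self.names) if n == term.name]

    def predict_linear(self, Xnew: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Linear predictor and its delta-method SE at new design rows."""
        M = Xnew[self.names].to_numpy(dtype=float)
        eta = M @ self.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", M, self.cov, M))
        return eta, se

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "estimate": self.params,
            "se": self.bse,
            "statistic": self.statistic,
            "p_value": self.pvalues,
        })

    def to_csv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, index=False)

    def info_dict(self) -> dict:
        return {
            "family": self.family,
            "link": self.link,
            "nobs": int(self.nobs),
            "df_resid": int(self.df_resid),
            "deviance": float(self.deviance),
            "pearson_chi2": float(self.pearson_chi2),
            "dispersion": float(self.dispersion),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.info_dict(), indent=2))


def fit_ols(X: pd.DataFrame, y: pd.Series, data: pd.DataFrame | None = None) -> FitResult:
    """Ordinary least squares with t-based Wald inference.

    ``sigma^2`` is estimated as RSS / (n - p); the coefficient covariance is
    ``sigma^2 (X'X)^{-1}``.
    """
    M = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = M.shape
    if n <= p:
        raise DegeneracyError(f"need n > p (n={n}, p={p})")
    xtx = M.T @ M
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError("singular X'X") from exc
    beta = xtx_inv @ (M.T @ yv)
    resid = yv - M @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    return FitResult(
        names=list(X.columns), terms=list(X.attrs.get("terms", [])),
        params=beta, cov=sigma2 * xtx_inv, df_resid=n - p, nobs=n,
        family="gaussian", link="identity", deviance=rss,
        pearson_chi2=rss, dispersion=sigma2, statistic_kind="t",
        X=X, y=pd.Series(yv, index=X.index),
        data=data if data is not None else X,
        fittedvalues=M @ beta,
    )


def _binom_deviance(y, mu, n) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(n * (t1 + t2)))


def fit_irls_binomial(X: pd.DataFrame, alive_dead: pd.DataFrame,
                      data: pd.DataFrame | None = None,
                      tol: float = 1e-9, max_iter: int = 100) -> FitResult:
    """Logit-link binomial MLE by iteratively reweighted least squares.

    Starts at empirical logits with the Haldane 0.5 continuity correction;
    converged when the largest coefficient change drops below ``tol``.
    Quasi-complete separation (fitted probabilities escaping to 0/1 with
    ever-growing coefficients) is reported as a warning and flag rather
    than an error, since small grouped datasets hit it legitimately.
    """
    M = X.to_numpy(dtype=float)
    alive = np.asarray(alive_dead.iloc[:, 0], dtype=float)
    dead = np.asarray(alive_dead.iloc[:, 1], dtype=float)
    n = alive + dead
    if np.any(n < 1):
        raise ValueError("every row needs alive + dead >= 1")
    y = alive / n
    nobs, p = M.shape
    mu = (alive + 0.5) / (n + 1.0)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(p)
    trace: list[tuple[int, float, float]] = []
    converged = False
    deviance = np.inf
    for it in range(1, max_iter + 1):
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        xtwx = M.T @ (w[:, None] * M)
        try:
            beta_new = np.linalg.solve(xtwx, M.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise DegeneracyError("singular weighted normal equations") from exc
        step = float(np.max(np.abs(beta_new - beta))) if it > 1 else np.inf
        beta = beta_new
        eta = M @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        deviance = _binom_deviance(y, mu, n)
        trace.append((it, step, deviance))
        if step < tol:
            converged = True
            break
    separation = bool(np.max(np.abs(eta)) > 25.0)
    if not converged:
        if separation:
            warnings.warn("quasi-complete separation: coefficients diverging",
                          SeparationWarning, stacklevel=2)
        else:
            raise ConvergenceError(
                f"IRLS did not converge in {max_iter} iterations", trace)
    elif separation:
        warnings.warn("fitted probabilities numerically 0 or 1",
                      SeparationWarning, stacklevel=2)
    w = n * mu * (1 - mu)
    cov = np.linalg.inv(M.T @ (w[:, None] * M))
    pearson = float(np.sum(n * (y - mu) ** 2 / (mu * (1 - mu))))
    df_resid = nobs - p
    return FitResult(
        names=list(X.columns), terms=list(X.attrs.get("terms", [])),
        params=beta, cov=cov, df_resid=df_resid, nobs=nobs,
        family="binomial", link="logit", deviance=deviance,
        pearson_chi2=pearson, dispersion=1.0, statistic_kind="z",
        X=X, y=alive_dead, data=data if data is not None else X,
        fittedvalues=mu, weights=n, converged=converged,
        separation=separation, n_iter=len(trace),
    )


def gof_overdispersion(fit: FitResult) -> dict:
    """Residual-deviance and Pearson goodness-of-fit tests for a binomial fit.

    Both statistics are referred to the upper tail of chi-square on the
    residual df; ``phi`` is the Pearson dispersion X^2 / df_resid.
    """
    if fit.family not in ("binomial", "quasibinomial"):
        raise ValueError("goodness-of-fit dispersion tests apply to binomial fits")
    if fit.df_resid <= 0:
        raise ValueError("saturated model: residual df = 0, test undefined")
    return {
        "deviance_p": float(stats.chi2.sf(fit.deviance, fit.df_resid)),
        "pearson_p": float(stats.chi2.sf(fit.pearson_chi2, fit.df_resid)),
        "phi": float(fit.pearson_chi2 / fit.df_resid),
    }


def quasify(fit: FitResult, phi: float | None = None) -> FitResult:
    """Quasibinomial correction: scale the covariance by the dispersion.

    Point estimates are untouched; SEs inflate by ``sqrt(phi)`` and Wald
    statistics become t on the residual df.
    """
    if fit.family not in ("binomial", "quasibinomial"):
        raise ValueError("quasify applies to binomial fits")
    if phi is None:
        phi = fit.pearson_chi2 / fit.df_resid
    return replace(fit, cov=fit.cov * phi, dispersion=float(phi),
                   family="quasibinomial", statistic_kind="t")


def _check_nested(full: FitResult, reduced: FitResult) -> int:
    extra = set(full.names) - set(reduced.names)
    if set(reduced.names) - set(full.names) or full.nobs != reduced.nobs:
        raise NestingError("reduced model is not nested in the full model")
    return len(extra)


def drop_term_test(full: FitResult, reduced: FitResult) -> float:
    """p-value for dropping the terms absent from ``reduced``.

    Gaussian: F test on residual sums of squares. Binomial: likelihood-
    ratio chi-square on the deviance difference. Quasibinomial: F test on
    the deviance difference scaled by the full model's dispersion.
    """
    ddf = _check_nested(full, reduced)
    if ddf == 0:
        return 1.0
    if full.family == "gaussian":
        f = ((reduced.deviance - full.deviance) / ddf) / (full.deviance / full.df_resid)
        return float(stats.f.sf(max(f, 0.0), ddf, full.df_resid))
    ddev = max(reduced.deviance - full.deviance, 0.0)
    if full.family == "binomial":
        return float(stats.chi2.sf(ddev, ddf))
    if full.family == "quasibinomial":
        f = (ddev / ddf) / full.dispersion
        return float(stats.f.sf(f, ddf, full.df_resid))
    raise ValueError(f"unsupported family {full.family!r}")
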