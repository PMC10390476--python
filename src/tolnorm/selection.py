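"""Backward elimination over a full-factorial candidate model.

Starting from the model containing every interaction among the candidate
variables, the least significant *droppable* term is removed one at a time
until every droppable term is significant at ``alpha``. A term is droppable
only if no retained term contains it (the marginality principle): main
effects stay in the model as long as any interaction involving them
survives. The replicate blocking factor, when offered, enters as a main
effect only and is never crossed with the treatment variables.

Drop tests follow the family: F tests on residual sums of squares for
Gaussian fits, likelihood-ratio chi-square on deviance differences for
binomial fits, and F tests on dispersion-scaled deviance differences for
quasibinomial fits. With the default ``auto`` policy, elimination runs on
the binomial likelihood and the *final* model is checked for
overdispersion (deviance and Pearson goodness of fit); if either test
rejects at ``alpha`` the final model's inference is quasibinomial. Setting
``gof_per_step`` re-checks dispersion at every step and switches the drop
tests to quasibinomial F tests as soon as overdispersion appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

import math
import warnings

from .glm import (DegeneracyError, FitResult, Term, build_design, drop_term_test,
                  fit_irls_binomial, fit_ols, gof_overdispersion, quasify)

__all__ = ["EliminationTrace", "TraceStep", "full_factorial_terms", "backward_eliminate"]


@dataclass(frozen=True)
class TraceStep:
    step: int
    term: Term
    p_value: float
    action: str  # dropped | retained


@dataclass
class EliminationTrace:
    """Audit record of a backward-elimination run; replays to the final model."""

    steps: list[TraceStep] = field(default_factory=list)
    final_terms: list[Term] = field(default_factory=list)
    family: str = ""
    gof: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": s.step, "term": s.term.name, "p_value": s.p_value, "action": s.action}
            for s in self.steps
        ])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def full_factorial_terms(candidate_vars) -> list[Term]:
    """All interactions among the candidates; replicate as main effect only."""
    cands = list(dict.fromkeys(candidate_vars))
    if not cands:
        raise ValueError("empty candidate variable set")
    crossed = [v for v in cands if v != "Replicate"]
    terms = [Term(combo) for k in range(1, len(crossed) + 1)
             for combo in combinations(crossed, k)]
    if "Replicate" in cands:
        terms.append(Term({"Replicate"}))
    return sorted(terms)


def _fit(table, terms, response):
    if response == "load":
        X, y = build_design(table, terms, "load")
        return fit_ols(X, y, data=getattr(table, "data", table))
    X, y = build_design(table, terms, "alive_dead")
    return fit_irls_binomial(X, y, data=getattr(table, "data", table))


def _fit_unaliased(table, current: set[Term], response: str,
                   trace: EliminationTrace) -> FitResult:
    """Fit the working model, shedding aliased terms first if need be.

    Degenerate data patterns (e.g. every cleared infection sitting in one
    treatment group) can alias an interaction column with a lower-order
    one; such terms cannot be estimated and are removed up front, highest
    order first, with an ``aliased`` entry in the trace.
    """
    while True:
        try:
            return _fit(table, current, response)
        except DegeneracyError as exc:
            names = {n if not n.startswith("Replicate[") else "Replicate"
                     for n in exc.aliased}
            victims = sorted((t for t in current if t.name in names),
                             reverse=True)
            if not victims:
                raise
            victim = victims[0]
            warnings.warn(f"term {victim.name} aliased in this subset; removed "
                          "before elimination", stacklevel=3)
            current.discard(victim)
            trace.steps.append(TraceStep(0, victim, math.nan, "aliased"))


def _droppable(current: set[Term]) -> list[Term]:
    return sorted(t for t in current if not any(o.contains(t) for o in current))


def backward_eliminate(table, response: str, candidate_vars, alpha: float = 0.05,
                       family_policy: str = "auto",
                       gof_per_step: bool = False) -> tuple[FitResult, EliminationTrace]:
    """Backward-eliminate the full factorial model over ``candidate_vars``.

    Parameters
    ----------
    table:
        ExperimentTable (or model frame) holding the subset to analyse.
    response:
        ``"load"`` (Gaussian) or ``"alive_dead"`` (grouped binomial).
    candidate_vars:
        Variable names; every interaction among them (replicate excepted)
        forms the starting model.
    alpha:
        Retention threshold; a droppable term with drop-test p > alpha is
        removed (largest p first).
    family_policy:
        ``auto``: binomial elimination, quasibinomial correction of the
        final model when its goodness-of-fit tests reject at ``alpha``;
        ``binomial`` / ``quasibinomial`` force the family. Ignored for the
        load response.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    current: set[Term] = set(full_factorial_terms(candidate_vars))
    trace = EliminationTrace()
    step = 0
    fit_full = _fit_unaliased(table, current, response, trace)
    while current:
        test_full = fit_full
        if response == "alive_dead":
            if family_policy == "quasibinomial" or (
                    gof_per_step and family_policy == "auto"
                    and fit_full.df_resid > 0 and _overdispersed(fit_full, alpha)):
                test_full = quasify(fit_full)
        droppable = _droppable(current)
        tested = []
        for term in droppable:
            fit_reduced = _fit(table, current - {term}, response)
            p = drop_term_test(test_full, fit_reduced)
            tested.append((term, p, fit_reduced))
        # drop the largest p; ties broken toward higher order, then name
        tested.sort(key=lambda tp: (-tp[1], -tp[0].order, tp[0].name))
        term, p, fit_reduced = tested[0]
        step += 1
        if p > alpha:
            trace.steps.append(TraceStep(step, term, p, "dropped"))
            current.discard(term)
            fit_full = fit_reduced
        else:
            for t, pv, _ in sorted(tested, key=lambda tp: tp[0]):
                trace.steps.append(TraceStep(step, t, pv, "retained"))
            break
    else:
        fit_full = _fit(table, current, response)

    final = fit_full
    if response == "alive_dead":
        gof = None
        if final.df_resid > 0:
            gof = gof_overdispersion(final)
        if family_policy == "quasibinomial" or (
                family_policy == "auto" and gof is not None
                and (gof["deviance_p"] < alpha or gof["pearson_p"] < alpha)):
            final = quasify(final)
        trace.gof = gof
    trace.family = final.family
    trace.final_terms = sorted(current)
    return final, trace


def _overdispersed(fit: FitResult, alpha: float) -> bool:
    gof = gof_overdispersion(fit)
    return gof["deviance_p"] < alpha or gof["pearson_p"] < alpha
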