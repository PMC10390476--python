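"""Full concurrent resistance-tolerance analysis of an experiment table.

Resistance side: Gaussian models of pooled bacterial load. An across-days
model (candidates: blood, sucrose, day, plus the replicate block) and one
model per day post-infection (candidates: blood, sucrose) are backward-
eliminated; any retained significant main effect marks a resistance
difference, with lower load read as higher resistance.

Tolerance side: grouped binomial survival models on the logit scale. An
across-days model (candidates: blood, sucrose, day, bacterial load),
day-specific models (blood, sucrose, load) and blood-status-specific
models (sucrose, day, load) are eliminated the same way, each checked for
overdispersion and quasi-corrected when detected. A significant
interaction between bacterial load and a treatment variable (or day) is
the signature of a tolerance difference: the groups' survival-on-load
reaction norms have different slopes. Slopes themselves, for trajectory
plots, come from per-day survival ~ blood x load fits whose load slope per
blood level is extracted as a marginal trend (the day-specific interaction
is retained there even when non-significant, so every group x day cell has
a slope estimate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import ExperimentTable, subset
from .glm import FitResult, Term, build_design, fit_irls_binomial, gof_overdispersion, quasify
from .marginal import build_trajectory, emm_curve, marginal_slope, trajectory_frame
from .selection import EliminationTrace, backward_eliminate

__all__ = ["Finding", "ModelEntry", "AnalysisReport", "run_resistance_analysis",
           "run_tolerance_analysis", "run_analysis", "classify_findings",
           "fit_slope_models", "tolerance_slopes"]

LOAD = "BacterialLoad"


@dataclass(frozen=True)
class Finding:
    component: str      # resistance | tolerance
    variable: str       # Blood | Sucrose | Day
    scope: str          # e.g. "across days", "day 1", "non-blood-fed"
    direction: str      # human-readable statement
    estimate: float
    p_value: float

    def as_dict(self) -> dict:
        return {"component": self.component, "variable": self.variable,
                "scope": self.scope, "direction": self.direction,
                "estimate": self.estimate, "p_value": self.p_value}


@dataclass
class ModelEntry:
    """One fitted model of the battery, with its elimination audit trail."""

    label: str
    description: str
    fit: FitResult
    trace: EliminationTrace | None = None
    n_obs: int = 0

    def __post_init__(self):
        self.n_obs = self.fit.nobs


@dataclass
class AnalysisReport:
    alpha: float
    resistance: dict[str, ModelEntry] = field(default_factory=dict)
    tolerance: dict[str, ModelEntry] = field(default_factory=dict)
    slope_models: dict[int, ModelEntry] = field(default_factory=dict)
    findings: list[Finding] = field(default_factory=list)

    def findings_dicts(self) -> list[dict]:
        return [f.as_dict() for f in self.findings]

    def write(self, outdir: str | Path) -> None:
        """Serialize every model (coefficient CSV + info JSON), traces and findings."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for section, models in (("resistance", self.resistance), ("tolerance", self.tolerance)):
            for label, entry in models.items():
                stem = outdir / f"{section}_{label}"
                entry.fit.to_csv(f"{stem}.csv")
                entry.fit.to_json(f"{stem}.json")
                if entry.trace is not None:
                    entry.trace.to_csv(f"{stem}_trace.csv")
        for day, entry in self.slope_models.items():
            entry.fit.to_csv(outdir / f"slope_day{day}.csv")
        (outdir / "findings.json").write_text(
            json.dumps(self.findings_dicts(), indent=2))
        (outdir / "summary.txt").write_text(self.summary_text())

    def summary_text(self) -> str:
        lines = [f"Concurrent resistance-tolerance analysis (alpha = {self.alpha})", ""]
        for section, models in (("Resistance (bacterial load)", self.resistance),
                                ("Tolerance (survival vs load)", self.tolerance)):
            lines.append(section)
            for label, entry in models.items():
                terms = ", ".join(t.name for t in entry.fit.terms if t.order > 0) or "intercept only"
                lines.append(f"  {entry.description} [{entry.fit.family}, "
                             f"n={entry.n_obs}]: {terms}")
            lines.append("")
        lines.append("Findings")
        if not self.findings:
            lines.append("  none at this alpha")
        for f in self.findings:
            lines.append(f"  [{f.component}] {f.direction} "
                         f"(estimate {f.estimate:+.3f}, p = {f.p_value:.3g})")
        return "\n".join(lines) + "\n"


def _enough_groups(table: ExperimentTable) -> bool:
    return len(table.data[["blood", "sucrose"]].drop_duplicates()) >= 2


_RESIST_DIRECTION = {
    # variable -> (group when coefficient positive, contrast group)
    "Blood": ("blood-fed", "non-blood-fed"),
    "Sucrose": ("high-sucrose (10%)", "restricted-sucrose (1%)"),
}


def _resistance_findings(entry: ModelEntry, scope: str, alpha: float) -> list[Finding]:
    out = []
    fit = entry.fit
    pvals, params = fit.pvalues, fit.params
    for term in fit.terms:
        if term.order != 1 or term.name in ("Day", "Intercept") or "Replicate" in term.factors:
            continue
        idx = fit.term_slice(term)[0]
        if pvals[idx] < alpha:
            hi, lo = _RESIST_DIRECTION[term.name]
            loaded, resistant = (hi, lo) if params[idx] > 0 else (lo, hi)
            out.append(Finding(
                "resistance", term.name, scope,
                f"{resistant} females more resistant (lower load than {loaded}) {scope}",
                float(params[idx]), float(pvals[idx])))
    return out


def run_resistance_analysis(table: ExperimentTable, alpha: float = 0.05) -> dict[str, ModelEntry]:
    """Across-days and per-day load models via backward elimination."""
    models: dict[str, ModelEntry] = {}
    fit, trace = backward_eliminate(
        table, "load", ["Blood", "Sucrose", "Day", "Replicate"], alpha=alpha)
    models["across_days"] = ModelEntry("across_days", "load across days", fit, trace)
    for day in table.days:
        sub = subset(table, day=day)
        if not _enough_groups(sub):
            warnings.warn(f"day {day}: fewer than 2 treatment groups, skipped", stacklevel=2)
            continue
        fit, trace = backward_eliminate(sub, "load", ["Blood", "Sucrose"], alpha=alpha)
        models[f"day{day}"] = ModelEntry(f"day{day}", f"load at {day} dpi", fit, trace)
    return models


def run_tolerance_analysis(table: ExperimentTable, alpha: float = 0.05,
                           family_policy: str = "auto") -> dict[str, ModelEntry]:
    """Across-days, per-day and per-blood-status survival models."""
    models: dict[str, ModelEntry] = {}
    fit, trace = backward_eliminate(
        table, "alive_dead", ["Blood", "Sucrose", "Day", LOAD],
        alpha=alpha, family_policy=family_policy)
    models["across_days"] = ModelEntry("across_days", "survival across days", fit, trace)
    for day in table.days:
        sub = subset(table, day=day)
        if not _enough_groups(sub):
            warnings.warn(f"day {day}: fewer than 2 treatment groups, skipped", stacklevel=2)
            continue
        fit, trace = backward_eliminate(
            sub, "alive_dead", ["Blood", "Sucrose", LOAD],
            alpha=alpha, family_policy=family_policy)
        models[f"day{day}"] = ModelEntry(f"day{day}", f"survival at {day} dpi", fit, trace)
    for blood, label, desc in ((0, "nonblood", "survival, non-blood-fed"),
                               (1, "blood", "survival, blood-fed")):
        sub = subset(table, blood=blood)
        if len(sub) == 0:
            warnings.warn(f"no rows with blood={blood}, skipped", stacklevel=2)
            continue
        fit, trace = backward_eliminate(
            sub, "alive_dead", ["Sucrose", "Day", LOAD],
            alpha=alpha, family_policy=family_policy)
        models[label] = ModelEntry(label, desc, fit, trace)
    return models


def fit_slope_models(table: ExperimentTable, alpha: float = 0.05) -> dict[int, ModelEntry]:
    """Per-day survival ~ blood x load fits used for slope extraction.

    The blood x load interaction is kept regardless of significance so that
    each blood group on each day contributes a tolerance slope; the fit is
    quasi-corrected when its goodness-of-fit tests reject at ``alpha``.
    """
    out: dict[int, ModelEntry] = {}
    terms = [Term({"Blood"}), Term({LOAD}), Term({"Blood", LOAD})]
    for day in table.days:
        sub = subset(table, day=day)
        if sub.data["blood"].nunique() < 2:
            warnings.warn(f"day {day}: single blood group, slope model skipped", stacklevel=2)
            continue
        X, y = build_design(sub, terms, "alive_dead")
        fit = fit_irls_binomial(X, y, data=sub.data)
        if fit.df_resid > 0:
            gof = gof_overdispersion(fit)
            if gof["deviance_p"] < alpha or gof["pearson_p"] < alpha:
                fit = quasify(fit)
        out[day] = ModelEntry(f"slope_day{day}", f"blood x load survival at {day} dpi", fit)
    return out


def tolerance_slopes(slope_models: dict[int, ModelEntry]) -> pd.DataFrame:
    """Tidy marginal survival-on-load slopes: one row per blood level x day."""
    rows = []
    for day, entry in sorted(slope_models.items()):
        sl = marginal_slope(entry.fit, wrt=LOAD, by="Blood")
        for r in sl.itertuples(index=False):
            rows.append({"blood": int(r.level), "day": day,
                         "slope": r.slope, "se": r.se})
    return pd.DataFrame(rows)


_TOL_SCOPE_GROUP = {"nonblood": "non-blood-fed", "blood": "blood-fed"}


def _tolerance_findings(models: dict[str, ModelEntry], alpha: float) -> list[Finding]:
    """Significant load x variable interactions, mapped to slope contrasts.

    Sign convention: slopes live on the logit-survival scale, so a less
    negative (or more positive) survival-on-load slope means higher
    tolerance. A positive blood x load coefficient therefore reads
    "blood-fed higher tolerance"; a negative day x load coefficient reads
    "tolerance declines over time".
    """
    out = []
    for label, entry in models.items():
        fit = entry.fit
        pvals, params = fit.pvalues, fit.params
        for term in fit.terms:
            if LOAD not in term.factors or term.order < 2:
                continue
            idx = fit.term_slice(term)[0]
            if pvals[idx] >= alpha:
                continue
            est, p = float(params[idx]), float(pvals[idx])
            others = sorted(term.factors - {LOAD})
            if label == "across_days":
                scope = "across days"
            elif label.startswith("day"):
                scope = f"at {label[3:]} dpi"
            else:
                scope = f"in {_TOL_SCOPE_GROUP[label]} females"
            if others == ["Blood"]:
                direction = (f"blood-fed {'higher' if est > 0 else 'lower'} "
                             f"tolerance than non-blood-fed {scope}")
                var = "Blood"
            elif others == ["Day"]:
                direction = (f"tolerance {'increases' if est > 0 else 'declines'} "
                             f"over time {scope}")
                var = "Day"
            elif others == ["Sucrose"]:
                direction = (f"high-sucrose {'higher' if est > 0 else 'lower'} "
                             f"tolerance than restricted-sucrose {scope}")
                var = "Sucrose"
            else:
                direction = (f"effect of {' and '.join(others)} on tolerance "
                             f"varies ({term.name} interaction) {scope}")
                var = ":".join(others)
            out.append(Finding("tolerance", var, scope, direction, est, p))
    return out


def run_analysis(table: ExperimentTable, alpha: float = 0.05,
                 family_policy: str = "auto") -> AnalysisReport:
    """The full battery: resistance models, tolerance models, slopes, findings."""
    report = AnalysisReport(alpha=alpha)
    report.resistance = run_resistance_analysis(table, alpha=alpha)
    report.tolerance = run_tolerance_analysis(table, alpha=alpha,
                                              family_policy=family_policy)
    report.slope_models = fit_slope_models(table, alpha=alpha)
    for label, entry in report.resistance.items():
        scope = "across days" if label == "across_days" else f"at {label[3:]} dpi"
        report.findings.extend(_resistance_findings(entry, scope, alpha))
    report.findings.extend(_tolerance_findings(report.tolerance, alpha))
    return report


def classify_findings(report: AnalysisReport) -> list[str]:
    """Human-readable one-liners for every significant effect."""
    return [f.direction for f in report.findings]


def report_outputs(report: AnalysisReport, table: ExperimentTable) -> dict[str, pd.DataFrame]:
    """Tidy curve and trajectory frames for downstream plotting."""
    slopes = tolerance_slopes(report.slope_models)
    traj = trajectory_frame(build_trajectory(table, slopes))
    curves = []
    for day, entry in sorted(report.slope_models.items()):
        c = emm_curve(entry.fit, by="Blood", scale="response")
        c.insert(0, "day", day)
        curves.append(c)
    curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    return {"trajectory": traj, "curves": curve_df, "slopes": slopes}
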