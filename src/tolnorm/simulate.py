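"""Synthetic infection experiments with known ground truth.

The generator emulates the data structure the analysis assumes: four diet
groups (blood meal yes/no x sucrose 10%/1%), five replicate experiments,
observations at 1, 3 and 5 days post-infection. Per insect, log10 CFU is
Gaussian around a group-and-day mean; four sampled individuals per cage-day
pass through a simulated dilution-plating observation process (Poisson
colony counts on plates at 1, 1e-2 and 1e-4, saturation above a countable
maximum) and are pooled by their median. Cage survival is binomial (or
beta-binomial, for extra-binomial dispersion) with a logit-linear mean in
day, blood status, the cage's pooled transformed load, and all their
interactions — the default coefficients are the fitted across-days survival
model of the study this design emulates, so parameter-recovery experiments
run at a realistic effect-size regime.

Survival depends on the cage's *pooled median* load, not the individual
loads: the analysis regresses cage survival on the sampled median, and the
generator mirrors that structural assumption.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExperimentTable, from_dataframe
from .quantify import (DEFAULT_COUNTABLE_MAX, DEFAULT_DILUTIONS, PlateSet,
                       QuantificationError, cfu_per_mosquito, pool_median)

__all__ = ["GenerativeParams", "simulate_individual_loads", "simulate_survival",
           "simulate_plates", "observe_cfu", "simulate_experiment"]

#: default logit-survival coefficients (across-days fitted model of the
#: emulated study): Day, Blood, load and all interactions
DEFAULT_SURVIVAL_COEF = {
    "Intercept": 1.34,
    "Day": -0.17,
    "Blood": 0.93,
    "BacterialLoad": 0.14,
    "Day:Blood": -0.22,
    "Day:BacterialLoad": -0.07,
    "Blood:BacterialLoad": -0.24,
    "Day:Blood:BacterialLoad": 0.09,
}

#: default log10-load model: intercept/day/sucrose from the across-days
#: load fit, plus the day-1-only blood effect from the day-1 fit
DEFAULT_LOAD_COEF = {
    "Intercept": 4.01,
    "Day": -1.04,
    "Sucrose": 3.81,
    "Blood@Day1": -3.67,
}


@dataclass
class GenerativeParams:
    """Ground-truth parameters of a simulated experiment.

    Load coefficients act on log10 CFU per insect; survival coefficients
    act on the logit of per-insect survival probability given the cage's
    pooled load on the ``log10(CFU + 1)`` scale. ``phi_gen`` >= 1 sets the
    target Pearson dispersion of cage survival (1 = exactly binomial;
    above 1, a beta-binomial with intraclass correlation
    ``(phi_gen - 1) / (cage_size - 1)``). ``missing_rate`` is the fraction
    of cage-day cells never observed (default 4/60, so the default design
    yields 56 rows).
    """

    n_replicates: int = 5
    days: tuple[int, ...] = (1, 3, 5)
    n_sampled: int = 4
    cage_size: int = 25
    load_coef: dict = field(default_factory=lambda: dict(DEFAULT_LOAD_COEF))
    load_sigma: float = 1.2
    cage_sigma: float = 2.8
    load_log10_max: float = 9.0
    survival_coef: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL_COEF))
    phi_gen: float = 1.0
    dose_mean: float = 312.0
    dose_sd: float = 13.0
    missing_rate: float = 4.0 / 60.0
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    countable_max: int = DEFAULT_COUNTABLE_MAX
    volume_scale: float = 1.0
    observe_plates: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phi_gen < 1.0:
            raise ValueError("phi_gen must be >= 1")
        if min(self.load_sigma, self.cage_sigma, self.dose_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.cage_size < 1 or self.n_sampled < 1:
            raise ValueError("cage_size and n_sampled must be >= 1")

    def truth(self) -> dict:
        d = asdict(self)
        d["days"] = list(self.days)
        d["dilutions"] = list(self.dilutions)
        return d


def _load_mean(params: GenerativeParams, blood: int, sucrose: int, day: int) -> float:
    c = params.load_coef
    mu = c["Intercept"] + c["Day"] * day + c["Sucrose"] * sucrose
    if blood and day == 1:
        mu += c.get("Blood@Day1", 0.0)
    return mu


def simulate_individual_loads(params: GenerativeParams, blood: int, sucrose: int,
                              day: int, rng: np.random.Generator,
                              n: int | None = None,
                              cage_effect: float = 0.0) -> np.ndarray:
    """Per-insect CFU: ``round(10 ** N(mu + cage_effect, sigma))``.

    ``cage_effect`` is the cage's shared deviation on the log10 scale
    (drawn with SD ``cage_sigma`` by :func:`simulate_experiment`): most
    load variation in grouped infection data sits between cages and
    replicates, not among the handful of individuals sampled from one
    cage. log10 values are capped at ``load_log10_max`` (a carrying
    capacity); draws below 0 round to sub-single-colony CFU, i.e. a
    cleared infection, and the downstream ``log10(CFU + 1)`` transform
    keeps those finite.
    """
    n = params.n_sampled if n is None else n
    mu = _load_mean(params, blood, sucrose, day) + cage_effect
    x = rng.normal(mu, params.load_sigma, size=n)
    x = np.minimum(x, params.load_log10_max)
    return np.maximum(np.round(10.0**x), 0.0)


def simulate_inoculum(params: GenerativeParams, rng: np.random.Generator,
                      n: int = 1) -> np.ndarray:
    """Injected dose per insect, CFU (calibration: mean 312, SD 13).

    The inoculum is what every insect starts with at day 0; the load model
    describes the later (1-5 dpi) outgrowth and is not anchored to it.
    """
    return np.maximum(np.round(rng.normal(params.dose_mean, params.dose_sd, size=n)), 0.0)


def survival_linear_predictor(params: GenerativeParams, load: float,
                              blood: int, day: int) -> float:
    """Logit survival at a cage's pooled (transformed) load."""
    c = params.survival_coef
    return (c["Intercept"] + c["Day"] * day + c["Blood"] * blood
            + c["BacterialLoad"] * load
            + c["Day:Blood"] * day * blood
            + c["Day:BacterialLoad"] * day * load
            + c["Blood:BacterialLoad"] * blood * load
            + c["Day:Blood:BacterialLoad"] * day * blood * load)


def simulate_survival(params: GenerativeParams, load: float, blood: int, day: int,
                      rng: np.random.Generator) -> tuple[int, int]:
    """(alive, dead) counts for one cage.

    Binomial at ``phi_gen == 1``; otherwise the success probability is
    itself Beta-distributed with intraclass correlation chosen so the
    Pearson dispersion of the counts is approximately ``phi_gen``.
    """
    eta = survival_linear_predictor(params, load, blood, day)
    p = 1.0 / (1.0 + np.exp(-eta))
    n = params.cage_size
    if params.phi_gen > 1.0 and n > 1:
        rho = (params.phi_gen - 1.0) / (n - 1.0)
        rho = min(rho, 1.0 - 1e-9)
        conc = 1.0 / rho - 1.0
        p = rng.beta(p * conc, (1.0 - p) * conc)
    alive = int(rng.binomial(n, p))
    return alive, n - alive


def simulate_plates(cfu: float, params: GenerativeParams,
                    rng: np.random.Generator) -> PlateSet:
    """Dilution-plating observation of one homogenate.

    Colony counts are Poisson with mean ``cfu * dilution / volume_scale``;
    plates above the countable maximum are flagged uncountable (their raw
    count retained, as a saturated lawn would still be recognized as such).
    """
    if cfu < 0:
        raise ValueError("cfu must be non-negative")
    counts, flags = [], []
    for d in params.dilutions:
        c = int(rng.poisson(cfu * d / params.volume_scale))
        counts.append(c)
        flags.append(c > params.countable_max)
    return PlateSet(counts=tuple(counts), dilutions=tuple(params.dilutions),
                    uncountable=tuple(flags), volume_scale=params.volume_scale)


def observe_cfu(cfu_true: float, params: GenerativeParams,
                rng: np.random.Generator) -> float:
    """True CFU -> plated -> quantified CFU.

    When every plate saturates (possible at extreme loads with a fixed
    dilution series), the most dilute plate's raw count is used anyway —
    the bench equivalent of estimating from a crowded plate rather than
    discarding the sample.
    """
    if not params.observe_plates:
        return float(cfu_true)
    plates = simulate_plates(cfu_true, params, rng)
    try:
        return cfu_per_mosquito(plates, params.countable_max)
    except QuantificationError:
        d = plates.dilutions[-1]
        return plates.counts[-1] * (1.0 / d) * params.volume_scale


def simulate_experiment(params: GenerativeParams,
                        seed: int | None = None) -> tuple[ExperimentTable, dict]:
    """A complete synthetic experiment table plus its ground-truth record.

    Deterministic given ``seed`` (falls back to ``params.seed``). A fixed
    number of cage-day cells — ``round(missing_rate * n_cells)`` — is
    dropped uniformly at random, mirroring occasional unobserved cells in
    real designs.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    cells = [(rep, blood, suc, day)
             for rep in range(1, params.n_replicates + 1)
             for blood in (0, 1)
             for suc in (0, 1)
             for day in params.days]
    n_drop = int(round(params.missing_rate * len(cells)))
    if n_drop:
        drop_idx = set(rng.choice(len(cells), size=n_drop, replace=False).tolist())
        cells = [c for i, c in enumerate(cells) if i not in drop_idx]
    rows = []
    for rep, blood, suc, day in cells:
        cage_effect = float(rng.normal(0.0, params.cage_sigma))
        true_cfus = simulate_individual_loads(params, blood, suc, day, rng,
                                              cage_effect=cage_effect)
        observed = [observe_cfu(c, params, rng) for c in true_cfus]
        median_cfu, _ = pool_median(observed, n_expected=params.n_sampled)
        load_t = float(np.log10(median_cfu + 1.0))
        alive, dead = simulate_survival(params, load_t, blood, day, rng)
        rows.append({"replicate": rep, "day": day, "blood": blood, "sucrose": suc,
                     "alive": alive, "dead": dead, "load_cfu": median_cfu})
    table = from_dataframe(pd.DataFrame(rows), load_transform="log10p1",
                           source=f"simulated(seed={seed})")
    truth = {"params": params.truth(), "seed": seed,
             "survival_coef": dict(params.survival_coef),
             "load_coef": dict(params.load_coef)}
    return table, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
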