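# Methods

This note records the statistical procedures, the calibration of the
synthetic-experiment generator, and the design decisions taken where the
problem left genuine freedom. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The unit of observation is a *cage-day*: one replicate experiment × one
diet group (blood meal 0/1 × sucrose concentration 0 = 1%, 1 = 10%) × one
day post-infection (1, 3, 5). Each row carries `(alive, dead)` counts for
the cage and the pooled bacterial load of four sampled individuals. Load is
stored on a configurable transform of median CFU; the default is
`log10(CFU + 1)`, chosen because (a) treatment effects on microbial growth
are multiplicative, so coefficients of a few units on a log₁₀ scale are
the natural effect size, and (b) the `+1` keeps cleared infections
(0 CFU) finite. The transform is recorded in the table's metadata and
inverted on write, so a written table round-trips exactly.

Treatment codings follow the direction conventions of the system the
package is calibrated to: `sucrose = 1` is the *high* (10%) diet and
`blood = 1` is blood-fed, so a positive sucrose coefficient on load means
the high-sugar diet carries more bacteria, and a negative blood
coefficient means blood-fed females carry fewer. Day enters all models as
a numeric covariate with a single slope. Missing cage-day cells are
simply absent (the emulated design observes 56 of 60 cells).

## CFU quantification

Each homogenate is plated undiluted and at 10⁻² and 10⁻⁴. The
least dilute plate whose colony count lies in `[1, countable_max]`
(default 300, the standard plate-count ceiling; the source protocol states
no threshold) yields `CFU = count / dilution × volume_scale`. If every
usable plate reads zero the infection is scored as cleared (0 CFU); if no
plate is usable a quantification error is raised. `volume_scale` (homogenate
volume / plated volume) defaults to 1 because the plated volume is
unreported; it cancels in log-scale treatment contrasts and is recorded
when set. Per-cage load is the median of the four individuals; quantiles
use linear interpolation (even-n median = mean of middle two), and the
interquartile range reported with it uses the same convention.

## Model fitting

*Gaussian side.* Ordinary least squares; `σ̂² = RSS/(n−p)`, covariance
`σ̂²(XᵀX)⁻¹`, t-based Wald inference on `n−p` df.

*Binomial side.* Grouped binomial logit GLM fit by iteratively reweighted
least squares. Start values are empirical logits with the Haldane 0.5
correction; convergence when the largest coefficient change falls below
1e-9 (max 100 iterations). Deviance and Pearson X² are reported with
z-based Wald inference. Quasi-complete separation (linear predictors
escaping beyond ±25 with diverging coefficients) is flagged and warned
about rather than raised: small grouped datasets hit it legitimately and
the fit remains usable for everything except the separated contrast.

*Overdispersion.* Both residual-deviance and Pearson goodness-of-fit
tests refer the statistic to χ² on the residual df. The dispersion is
estimated as `φ = X²/df` (the Pearson estimator; the deviance-based
estimator is biased at the small group counts typical here). Quasibinomial
correction multiplies the covariance by φ and switches Wald statistics to
t on the residual df; point estimates are untouched, which the tests
assert exactly.

*Drop tests.* Gaussian: partial F on residual sums of squares (equal to
the squared-t p-value for single-column drops, asserted to 1e-10).
Binomial: likelihood-ratio χ² on the deviance difference. Quasibinomial:
F on the deviance difference scaled by `Δdf × φ_full`.

## Backward elimination

Starting from the full factorial model over the candidate variables, the
droppable term (one not contained in any retained term) with the largest
drop-test p-value is removed while that p exceeds α (default 0.05, the
significance level used throughout; ties break toward the higher-order
term, then lexicographically). Marginality is enforced structurally, so
`α = 1` returns the full model and `α = 0` the intercept. The replicate
label may be offered as a blocking main effect for load models; it is
never crossed with treatments.

For survival responses the default `auto` policy eliminates on the
binomial likelihood and tests the *final* model for overdispersion,
refitting quasibinomial when either goodness-of-fit test rejects at α;
`gof_per_step=True` instead re-checks at every step and switches the drop
tests to quasibinomial F tests (with φ from the current working model) as
soon as overdispersion appears. Whether re-testing happened per step or
only on final models is not documented for the source analysis; final-model
testing is the default because it is the more reproducible convention.

Degenerate data patterns can alias a column (e.g. when every cleared
infection sits in one diet group, `Sucrose × Load` duplicates `Load`).
Aliased terms cannot be estimated and are removed before elimination
starts, highest order first, logged in the trace as `aliased` — the
analogue of R's `NA` coefficients.

A note on stepwise type-I behaviour: with seven candidate terms the
probability that *some* spurious term survives a null experiment is
roughly `1 − 0.95⁷ ≈ 30%` — that is a property of every α = 0.05 stepwise
procedure, not of this implementation. The meaningful per-term error rate
(a given spurious term retained as itself significant) is ≈5% and is what
the acceptance checks bound at 10%.

## Marginal means, trends and trajectories

The reference grid crosses the grouping factor's levels with 25 evenly
spaced load values spanning the observed range; other model variables are
held at their observed means. Curves are reported on the response scale
through the inverse logit, with delta-method SEs
(`SE_response = SE_linear · μ(1−μ)`). Marginal slopes are central
difference quotients `(η(x+h) − η(x−h))/2h` averaged over the grid
(`h` = range/1000), with SEs from the averaged gradient and the
coefficient covariance. For models linear in load the quotient is exact —
independent of `h` and grid density, equal to
`β_load + β_interaction · level` — which the tests assert to 1e-10; the
difference-quotient formulation is kept for generality (e.g. polynomial
load terms).

Slopes are reported on the linear-predictor (logit) scale, where the
group contrast in slopes *is* the fitted interaction coefficient: "higher
tolerance" means a less negative / more positive survival-on-load slope.
Trajectory points pair each blood group × day median load (with IQR;
resistance is conventionally plotted on a reversed load axis) with the
marginal slope from that day's `survival ~ blood × load` fit. The
interaction is retained in those per-day slope models regardless of
significance so that every group × day cell contributes a slope — on data
where the interaction is retained by elimination the two fits coincide.

## Synthetic-experiment generator

The generator emulates the target experimental design end to end and is
the basis of all calibration claims.

| parameter | default | meaning |
|---|---|---|
| `n_replicates` | 5 | replicate experiments |
| `days` | (1, 3, 5) | observation days post-infection |
| `cage_size` | 25 | alive+dead per cage-day |
| `n_sampled` | 4 | individuals pooled for the load median |
| `load_coef` | 4.01, −1.04 (day), 3.81 (sucrose), −3.67 (blood, day 1 only) | log₁₀-load model, the printed load-model estimates |
| `cage_sigma` | 2.8 | between-cage SD of log₁₀ load |
| `load_sigma` | 1.2 | within-cage per-mosquito SD |
| `load_log10_max` | 9 | carrying-capacity cap on log₁₀ load |
| `survival_coef` | printed across-days survival estimates (three-way 0.09) | logit-survival truth |
| `phi_gen` | 1 | target Pearson dispersion of cage survival |
| `dose_mean/sd` | 312 / 13 | injected inoculum CFU |
| `missing_rate` | 4/60 | unobserved cage-day cells (→ 56 rows) |

Per-mosquito log₁₀ CFU is Gaussian around the group-day mean plus a
shared cage effect, capped at the carrying capacity; draws below zero
round to 0 CFU (cleared). The noise is split into cage and individual
components because the printed day-specific SEs imply a cage-level
residual SD of roughly 1.3–3.6 (≈3.2 pooled), far more than four
same-cage individuals plausibly spread: most load variance in such data
sits between cages and replicates. With the defaults the realized
cage-median residual SD is ≈2.1 — the floor at 0 and the cap absorb the
rest — which the package treats as the operative study condition.

Observation passes each true CFU through Poisson plate counts at the
three dilutions (mean `cfu × dilution / volume_scale`), flags counts above
the countable maximum as saturated, and quantifies via the least-dilute-
countable rule. When all plates saturate, the most dilute plate's raw
count is used (the bench equivalent of reading a crowded plate); the
strict quantifier alone would raise.

Cage survival is binomial in `cage_size` with logit-linear mean in day,
blood, and the cage's *pooled observed* load — the same quantity the
analysis regresses on, a deliberate structural assumption (the joint
distribution of individual loads and survival within a cage is not
observable in data of this shape). For `phi_gen > 1` the success
probability is Beta-distributed with intraclass correlation
`(φ−1)/(n−1)`, giving Pearson dispersion ≈ φ (recovered to ≈1% at φ = 3
over 200 simulations by the acceptance script).

What passing tests on these simulations do *not* show about real data:
real load distributions are heavier-tailed and day-heterogeneous than a
single log-normal; real survival may depend on unobserved individual
loads rather than the cage median; and the linear day trend in the
default load truth overstates late clearance relative to the printed
day-specific intercepts, which is why the three-way-interaction recovery
power at the default truth is ≈65–75% rather than the ≈80%+ a
shallower day trend would give. Treatment-effect recovery on the *load*
side is attenuated by the floor/cap truncation (a fitted sucrose effect
of ≈2.6–3.0 against a generative 3.81 is expected); survival-side
coefficients are unbiased because generation and analysis condition on
the same observed load.

## Numerical conventions

Design matrices carry one column per term; interaction columns are
row-wise products (all treatments are 0/1, day and load numeric), the
replicate block expands to dummy columns against its first level.
Rank deficiency raises with the aliased columns named, except on
prediction grids where constant columns are expected. Quantiles are
linear-interpolation throughout. IRLS tolerance 1e-9 on coefficients;
Newton-oracle agreement is asserted at 1e-8. All simulation entry points
take a single integer seed through `numpy.random.default_rng`; identical
seed and parameters give byte-identical CSV output.

## Known limitations

- No random effects: replicate enters as a fixed block for load models
  and not at all for survival models, mirroring the analysis convention
  this package reproduces rather than best current practice (a GLMM).
- Quasi-likelihood handles overdispersion only through a scalar φ;
  beta-binomial likelihoods are not fit, only simulated.
- Links other than identity/logit, Firth correction for separation, and
  AIC-based selection are out of scope.
- Point tolerance (vigor at a fixed dose) is deliberately not estimated;
  the approach is range tolerance over the observed load span.
- The day-3 tolerance slope model retains a non-significant interaction
  by design; its slope SEs are correspondingly wide.
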