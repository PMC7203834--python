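# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `geoaft`. It is the package's own account of its science;
every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Cohort construction

Eligibility for the disease-specific mortality analysis requires age at
diagnosis ≥ 40 (and present) and a resolved Gleason score ≥ 6, with an
exception for cases missing a Gleason score whose resolved tumor stage is
T3 or T4. Gleason score and stage are resolved **pathology-first**: the
pathology value is used whenever documented, otherwise the clinical value,
otherwise missing. Excluded cases are tallied under exactly one reason.
Because a record can violate several rules at once, the tally uses a fixed
precedence — age first, then Gleason < 6, then missing-Gleason-without-
T3/T4 — chosen so tallies are deterministic; the ordering itself is a
design choice, not an epidemiological claim.

Tumor aggressiveness is pattern-specific: *less aggressive* requires
Gleason 6 or 7 with 3+4 patterns **and** stage T1–T2 **and** no distant
metastasis; *more aggressive* is Gleason 7 with 4+3, Gleason ≥ 8, stage
T3–T4, or metastasis. A Gleason 7 without pattern detail cannot be placed
and is labelled unknown, as is Gleason 6 with unknown stage or metastasis.
County region crosses the Appalachia flag with the USDA Rural-Urban
Continuum Code (RUCC < 4 = metro/urban).

The descriptive summary reports means (SD) and counts (column %), with
uncorrected chi-square tests for categorical variables (most tables here
are multi-level, where the continuity correction does not apply) and
one-way ANOVA for continuous ones. Unknown/missing categories stay in the
summary table but are excluded from the tests and from model fits.

## Age-standardized incidence

Directly standardized rates use the 2000 U.S. standard million restricted
to the bands fully at or above the age floor (default 40) and renormalized
to sum to one; bands straddling the floor are dropped, not prorated, which
is the natural reading of "standard weights corrected for a subpopulation
aged 40+" with integer bands. Confidence intervals are the Fay–Feuer gamma
construction, the standard registry implementation of "the gamma method";
in the single-stratum, unit-weight limit it reduces to the exact Poisson
gamma interval, which the tests verify to 1e-10.

## Nonparametric survival

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
`lifelines` behind the module surface; disease-specific deaths are events
and other-cause deaths are censored. Pointwise confidence intervals use
the log(−log) (exponential Greenwood) transform — the registry convention —
since bounds are then guaranteed to stay inside [0, 1]. Ties between an
event and a censoring at the same time follow the events-first convention.
Survival at a horizon is the curve value at the last observed time ≤ the
horizon; horizons beyond follow-up return the terminal value with a
truncation flag rather than an error.

One property often misstated deserves a note: adding a censored
observation *after the last event time* does change the log-rank statistic
(the subject is in every event-time risk set); the inert operation is a
censored observation *before the first* event time, and that is what the
tests assert.

## The spatial AFT model

For case *i* in county *c(i)*: `log T_i = μ + x_i'β + W_c(i) + σ ε_i`.

* **Baseline error law.** Log-normal by default; this gives fully
  conjugate Gibbs updates and stable mixing. A Weibull baseline (standard
  minimum extreme-value errors) is available behind a flag and is fitted
  by Metropolis-within-Gibbs with step sizes adapted during burn-in.
* **Frailty prior.** Intrinsic CAR with precision τ over the county
  adjacency graph. The prior is improper: its null space contains one flat
  direction per connected component. The sampler therefore recenters the
  field every sweep within each non-singleton component and then globally,
  so every retained draw sums to zero and component levels cannot drift
  against the intercept or against county-level covariates. Isolated
  counties get an exchangeable N(0, 1/τ) prior. Without the per-component
  centering, a disconnected graph makes group contrasts non-identified and
  the posterior wanders to the vague prior — this is observable and is why
  the centering is per component, not merely global.
* **Censoring.** Latent log-times for censored cases are imputed each
  sweep from the model normal truncated below at the censoring log-time.
  The truncated-normal sampler uses inverse-CDF sampling in the body and a
  shifted-exponential tail approximation beyond 6 SDs (accurate there and
  immune to u → 1 round-off).
* **Priors (all configurable).** β, μ ~ N(0, 10⁴); σ² ~ InvGamma(0.01,
  0.01); τ ~ Gamma(0.5, 0.0005). These are the standard vague choices for
  CAR survival models. τ's conjugate update uses the ICAR quadratic form
  with rank = (nodes − components) + isolated nodes.
* **Times.** Follow-up is in months; zero or implausibly small times are
  floored at 0.5 month before logging (diagnosis-month granularity in
  registries).
* **MCMC defaults.** 12,000 iterations, 2,000 burn-in, thinning 2, one
  chain. Convergence is monitored by coefficient effective sample size and
  Geweke z-scores; suspicious chains trigger a RuntimeWarning (min ESS
  < 100 or |z| > 3), never silent acceptance. Tests and the acceptance
  script run shorter chains (600–4,000 iterations at n = 400–5,000), sizes
  chosen as the smallest at which the conjugate closed-form check and the
  recovery checks are stable.
* **DIC.** D̄ is the posterior mean of −2·log-likelihood (observed-data:
  density for events, survivor function for censored); D(θ̄) evaluates the
  deviance at the posterior means of all parameters; p_D = D̄ − D(θ̄).
* **Catchment model.** The catchment-restricted fit drops the catchment
  covariate and restricts both data and graph to catchment counties.

## Secondary assessment

Counties are classified into quartiles of posterior-mean frailty (Q4 =
highest = longest survival) by rank, ties broken by county id so the
classification is deterministic. Each factor is analyzed univariately as
the **outcome** of a spatial regression on the Q4-vs-Q1 indicator,
`factor_c = α + γ·1[Q4] + u_c + e_c`, with u an ICAR effect on the Q1∪Q4
induced subgraph. This direction — factor as outcome, frailty quartile as
exposure — yields one interpretable estimate per factor whose sign follows
the frailty convention (γ > 0: elevated where survival is longest); it is
flagged here because the reverse regression is equally defensible.
Flagged factors are natural-log transformed first; nonpositive values are
shifted by half the smallest positive observed value and the shift is
recorded. An entirely edgeless induced subgraph falls back to the
independent-error model, flagged. Significance is 95% credible-interval
exclusion of zero with no multiplicity adjustment by default (an optional
Benjamini–Hochberg pass is provided); on pure-noise factors the realized
false-positive rate is near the nominal 5% (measured by the test suite).
Per-factor seeds derive from the factor *name*, so results do not depend
on column order.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
population:

* Event times follow the AFT model exactly, with frailties drawn from the
  ICAR distribution via eigendecomposition of the graph Laplacian.
* Censoring combines an administrative horizon (default 132 months, an
  11-year study window) with an exponential competing other-cause death
  time whose rate is solved by bisection to hit a target overall
  censoring fraction (default 0.85 — in an elderly cohort with high
  disease-specific survival, most follow-up ends without the event). If
  the target lies below the administrative floor the rate clamps at zero.
* Covariate margins (race, ethnicity, insurance, aggressiveness, nodes,
  treatment) default to a published registry cohort's descriptive table;
  Gleason patterns, stage and metastasis are synthesized **consistently
  with** the drawn aggressiveness class, and a small fraction of
  ineligible records (low Gleason, missing Gleason with low stage,
  under-40) is injected so the cohort stage has real work.
* County covariate tables are built as `effect · frailty + noise` (linked
  columns) or pure noise (null columns), with the truth in the column
  names.

What it does **not** emulate: the joint covariate distribution beyond
margins, PSA–Gleason correlation, screening behavior, county population
shares (case-to-county assignment uses configurable weights, uniform by
default), or calendar-time trends. Passing recovery tests therefore shows
the estimator is correct under its own assumptions — not that those
assumptions hold in any particular registry.

## Packaged fixtures

The 67-county Pennsylvania fixture ships an approximate, curated
queen-contiguity adjacency list and county attributes whose regional
margins match the published scheme (15 urban non-Appalachia / 22 urban
Appalachia / 30 rural Appalachia; a 28-county catchment split 9/9/10).
Exact catchment membership and RUCC codes are plausible stand-ins, not
authoritative data. Map export uses synthetic unit-square polygons; real
boundaries are out of scope.

## Known limitations

* Single-chain MCMC with ESS/Geweke diagnostics; multiple chains and
  R-hat are not built in.
* The Weibull baseline's random-walk sampler mixes more slowly than the
  log-normal Gibbs path and is intended for sensitivity checks.
* Complete-case analysis only; no imputation of missing risk factors.
* The secondary regression treats the estimated frailty quartiles as
  fixed, ignoring posterior uncertainty in the field (as the two-stage
  design implies).
* No proportional-hazards alternative and no spatial priors beyond
  ICAR.
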