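# Methods

## Trial-design model

A study of `D` days (default 730, anchored at a configurable calendar
origin, default 1 June) is partitioned into three half-open phases:
validation `[0, 273)`, randomisation `[273, 457)` and implementation
`[457, 730)`. Seven sites each have a *planned* (randomised) crossover day —
taking exactly three distinct step values — and an *actual* crossover day
inside the randomisation phase; in the default design four sites cross at
the first actual step, one at the second and two at the third, and actual
days differ from planned by one to two months in both directions. A
presentation on the crossover day itself counts as intervention (the
pathway is live from its implementation date). Exposure time is
`max(day − crossover, 0)`. Season is the meteorological quadruple (Winter =
Dec–Feb as the reference, Spring, Summer, Autumn) of the presentation's
calendar month. Cluster periods are site × calendar-month cells.

Two analysis populations restrict the data: *randomisation phase only*
(half-open day window) and *calendar matched*, which keeps
validation- and implementation-phase records whose calendar date falls
between 3 March and 3 September of any year. The boundary dates are treated
as inclusive (a "between A and B" read inclusively); this is configurable
because the convention is genuinely ambiguous, and no result here hinges on
the two boundary days.

## Outcome models

**Length of stay.** `log(los_hours)` is modelled by a Gaussian linear mixed
model with a site random intercept (exactly compound symmetry within site),
fixed effects for the intervention indicator, season dummies and a secular
trend, and the effect reported as the geometric mean ratio
`exp(beta_intervention)` with a Wald 95% CI. Estimation profiles the fixed
effects and residual variance out by generalised least squares (Woodbury
identity per cluster) and optimises the remaining variance-ratio
parameters; REML is the default (ML available). The implementation is
in-package because inverse-probability weighting needs per-row frequency
weights, which the usual Python mixed-model routines do not take; the
unweighted path is cross-checked against `statsmodels.MixedLM` in the test
suite to 1e-6 on coefficients.

**Safety event.** The rare binary endpoint is modelled by a logistic mixed
model. Per cluster, the random effect is integrated out of the product of
Bernoulli likelihoods against its Gaussian density; the integral is
approximated by adaptive Gauss–Hermite quadrature with nodes centred at the
conditional mode and scaled by the conditional curvature. One node is the
Laplace approximation, the default for the post-hoc model variants (it is
faster and, with between-site variance near zero, indistinguishable from
the quadrature); the pre-specified scalar-random-intercept models use
25 nodes by default. The random effect enters in scaled Cholesky form
`u = Lambda v`, so the zero-variance boundary is a smooth point of the
objective and degenerates exactly to plain logistic regression — variance
estimates at the boundary are reported as 0 with a flag, never as an error,
because that boundary is the expected regime here. The Laplace path has an
analytic gradient (including the mode's dependence on the parameters); the
quadrature path optimises from a Laplace warm start with numerical
gradients. Random-slope variants (intervention or time slope, unstructured
2×2 covariance) are Laplace-only, since the quadrature is implemented for
the scalar integral. A brute-force `scipy.integrate.quad` oracle validates
the quadrature to 1e-6 on small instances.

Fixed-effect covariances come from the penalised-likelihood information
profiled over the conditional modes (a Schur complement per cluster), the
same conditional approximation standard mixed-model software reports. All
intervals are Wald on the log scale, exponentiated for OR/GMR reporting.

**Weights** multiply per-row conditional log-likelihood contributions
(frequency-style). With constant weights and zero cluster variance this
leaves point estimates untouched and scales standard errors by the inverse
square root — the regime the IPTW invariance tests pin down. Robust
(sandwich) standard errors for IPTW are not implemented; the reported IPTW
intervals are model-based.

## The analysis catalogue

Eleven models `A`–`K` share the backbone (site random intercept,
intervention indicator) and vary population, timing source, secular trend,
season terms, exposure term and random-effect structure; the table in the
README and the `MODEL_CATALOGUE` mapping are the single source of truth,
asserted field-by-field in the tests. Numerical choices:

- Centred linear time is internally scaled to years so all coefficients are
  O(1); centring is on the midpoint of min/max presentation day of the
  analysis population. Centring and scaling provably do not move the
  intervention OR (tested).
- Cubic-spline trends use a natural cubic spline basis (truncated-power
  construction): interior knots at equally spaced quantiles (default 3),
  boundary knots at min/max, `n_knots + 1` columns, linear tails. For
  exposure-time splines the knots come from the quantiles of *positive*
  exposure, since control records pile up at zero.
- Categorical time uses 3-month bins from study start (8 bins over
  24 months), first *observed* bin as reference. Season and period dummies
  are coded over the levels present in the analysis population — a
  phase-restricted population may not contain the global reference level
  (the randomisation phase spans spring and summer only), in which case the
  first present level is the reference, exactly as factor coding would do.

Adjustment methods: direct covariates (age, sex, SIMD quintile entered
linearly; or the full 13-variable history + demographics list); regression
on the logit of a propensity score; or IPTW. The propensity score is a
site-random-intercept logistic model of the condition indicator on the 13
covariates, re-estimated on each restricted analysis population, with
fitted probabilities trimmed to `[1e-6, 1 − 1e-6]` and optional weight
truncation (off by default). The printed form of the IPTW weight in some
sources omits the division bars; the implemented weight is the standard
`Z/p + (1 − Z)/(1 − p)`, which is what inverse probability weighting means.

The approximate risk difference attached to safety fits is the average
marginal effect — the mean over patients of the model probability with the
intervention indicator switched on minus switched off, random effects at
zero — with a delta-method CI. This is one defensible construction among
several; it reproduces the closed form `p1 − p0` in a homogeneous
population and is tested against it.

## Synthetic cohorts

The parametric generator is the package's definition of the study
conditions: 31,492 presentations by default, uniform over the study window
with equal site weights (relative site sizes are not public; configurable),
age ~ Normal(59, 17) clipped to [18, 110], 45% female, equal SIMD
quintiles, history-flag prevalences set to plausible population values
(IHD 15%, MI 8%, CVD 5%, diabetes 10%, PCI 5%, CABG 3%, aspirin 20%,
lipid-lowering 25%, beta blocker 15%, ACE inhibitor 15%), log-normal length
of stay (geometric mean 10.1 h, log-SD 0.9) with intervention multiplier
0.78 and mild seasonal multipliers, and a Bernoulli safety event at 0.4%
baseline with site random-intercept SD 0 (the trial's between-site
variability was effectively zero; raise it for stress tests) and, by
default, no intervention effect. Optional per-day drift in covariate means
(additive in years for age, additive on the logit for binary flags)
exercises the adjustment methods. One integer seed drives everything;
identical seeds give byte-identical CSVs.

Replica mode forces the printed count identities instead of sampling them:
phase denominators and event totals, and the randomisation-phase condition
split, are exact; events are spread over cluster periods by a seeded draw
proportional to denominators, because the real cluster-period table is not
reconstructable — this is the one structural unknown, and it matters: any
model that leans on *where* in time the events sit (the secular trend, the
vertical contrast) will differ between the replica and the real data. The
replica reproduces count arithmetic, not model-based estimates. An optional
spike places exactly 7 events in one nominated randomisation-phase cell
(carved out of the phase total, so the grand totals still hold).

What passing tests on these cohorts do **not** show: recovery of the real
trial's model-based estimates, realistic within-site arrival patterns,
seasonality of the event rate, or correlated covariates — the generator's
covariates are mutually independent given the presentation day.

## Augmentation

The synthetic prior allocates patients equally across the 7 sites and
equally across the two days adjacent to each site's crossover (control side
at −1 day, intervention side at +1). Any remainder is distributed pair-wise
across sites in site order; an odd leftover is rounded *up* to a full pair
— never silently unbalanced — so per-side denominators match exactly and
the prior risk difference is identically zero. Events per site come from a
single Binomial(per-side count, 0.4%) draw applied to both sides, which
enforces the equal-events rule per site and overall by construction (a
rejection-sampling alternative would converge to the same law conditioned
on equality; the single-draw mechanism is the simplest that satisfies the
stated constraint). The prior-only risk-difference CI is a Newcombe score
interval (Wilson intervals combined); the calibration loop walks
`n = 500, 600, …` and returns the first prior whose CI fits within ±2
percentage points, re-checking the criterion on the returned dataset. The
calibrated size lands in the hundreds-to-low-thousands depending on the
Binomial draws. The pooled fit is the primary safety model with the global
intercept replaced by separate real/synthetic baselines — the only
full-rank reading of a no-intercept fit that adjusts for data type.
Synthetic patients' covariates are filled from the population model; they
are absorbed by the synthetic baseline in the unadjusted pooled fit.

On cohorts generated with a genuine effect, the pooled |log OR| shrinks
weakly monotonically as the prior grows. On the replica, whose event-time
placement is random, the prior's flat rate can also perturb the shared
secular-trend coefficient and nudge the OR either way — a caveat inherent
to pooling data that carry their own time structure.

## Sensitivity probes

Cluster-period modification relabels `safety_event` within one cell by a
seeded draw; denominators and all other cells are untouched. The
tipping-point search removes events cumulatively from a (condition, phase)
stratum — largest-count cluster periods first, ties by site order, then
seeded within the cell; a deterministic order that probes the dominant
cells first — refitting the chosen model at each step until the OR drops
below 1. Trajectories are weakly monotone up to refit noise (each refit
re-estimates the trend and variance components, so step-to-step wobble of
order 1% is tolerated in the tests). The median cluster-period event count
is computed over cells with at least one presentation, zero-event cells
included.

## Simulation harness

`simulate_null_study` / `recovery_study` generate independent cohorts and
fit the primary safety model per replicate (Laplace by default — at zero
between-site variance it coincides with the quadrature and is several-fold
faster), reporting the two-sided Wald rejection rate at the null, bias of
the log OR, 95% CI coverage at the truth, and mean CI width, each with
Monte-Carlo standard errors; replicates that fail to converge are excluded
and counted, and more than 10% of them aborts the study. The shipped checks
run 500 null replicates and 300 recovery replicates at the full cohort size
of 31,492 — large enough that a 3-Monte-Carlo-SE band around the nominal
5% / 95% is a meaningful test, small enough to run on a laptop in a couple
of minutes.

## Known limitations

- No GEE or autoregressive/unstructured-residual variants: with clusters of
  ~4,500 patients these model families are impractical here, and they are
  out of scope.
- IPTW interval estimates are model-based (no sandwich variance).
- The quadrature is scalar-only; random-slope models rely on Laplace.
- The replica's cluster-period allocation is one random draw among the many
  consistent with the phase totals; conclusions that depend on the
  within-phase placement of events are draw-specific by design.
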