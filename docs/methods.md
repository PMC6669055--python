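# Methods

This note documents the statistical models, the conventions and tie-break
rules, the synthetic-data generator that the tests exercise the pipeline
against, and the numerical choices. Everything quantitative quoted here is
computed by the test suite, the `analysis/` scripts or
`scripts/acceptance.py`.

## Anthropometric scoring and classification

Measurements are scored against an LMS (Box-Cox) growth reference:
`z = ((x/M)^L − 1)/(L·S)`, with the log-limit `z = ln(x/M)/S` used when
`|L| < 1e−7`. Both directions are implemented with `expm1`/`log1p`
formulations, so the compute∘invert round trip is exact to ≈1e−14 across
the full admissible parameter range, including L arbitrarily close to 0.
LAZ indexes length by age in days; WLZ indexes weight by length in cm
(recumbent-length convention throughout — the cohorts of interest are
under 24 months, so no standing-height correction is applied). Reference
curves are interpolated linearly in the index variable, which is adequate
at day/centimetre granularity and deterministic; lookups outside a
reference grid either raise or yield a missing z-score, by policy.

Classification thresholds are strict: wasted ⇔ WLZ < −2, stunted ⇔
LAZ < −2, concurrent ⇔ both, small MUAC ⇔ MUAC < 12.5 cm. Missing inputs
leave the corresponding flag undefined rather than false, so downstream
denominators count only classified children.

A bundled toy reference (smooth analytic L/M/S curves, 0–26 months in
monthly steps and 42–100 cm in 1-cm steps, both sexes) supports the tests
and the generator; real WHO tables in the same CSV schema are a drop-in
replacement. The toy curves are *not* the WHO standard and carry plausible
magnitudes only.

## Cleaning rules

1. **Implausible z-scores**: exclude visits with LAZ outside (−6, 6) or
   WLZ outside (−5, 5), strictly (the WHO flagging limits).
2. **Extreme change**: within each child's date-sorted sequence, any
   consecutive pair differing by more than 3 SD in LAZ or WLZ marks an
   outlier. The rule as usually stated does not say *which* member of the
   pair is the outlier; here the visit whose z lies farther from the
   child's own median z is excluded (robust and deterministic), ties going
   against the later visit, and the sweep repeats until no violating pair
   remains. The child's median is fixed at entry to the rule. The rule is
   applied to LAZ and WLZ separately; a visit flagged on either axis is
   excluded entirely.

Rules run in the order above; a participant whose visits are all excluded
is counted as an excluded participant. The report enforces the exact
conservation identity (input visits = output visits + per-rule
exclusions). One completed month of age = 365.25/12 days everywhere.

## Seasonal episodes

The wet ("hungry") season is July 1–October 31; the dry season November
1–June 30 of the following year, both endpoint-inclusive, tiling the
calendar. A child's first wet season is the wet window containing the
birth date (season of birth) or, for dry-season births, the next wet
window; the second wet season is the following year's window. Within a
window a child is wasted if the *median* of their WLZ observations there
is < −2 (even counts use the midpoint). The day-of-birth measurement
counts as an observation by default (`include_birth_visit` toggles this).
Children observed at least once in each of the three windows enter the
repeat-wasting logistic model (second-wet wasting on first-wet and dry
wasting).

## Prevalence by age

Visits are grouped by completed month of age 0–23. A child with several
measurements in one month is classified by the mean z within that month
(mean-then-classify, not classify-then-any), so each child counts once per
bin. The 20–24-month stunting outcome is defined on completed months
20–23: stunted iff the mean LAZ over the window's visits is < −2
(mirroring the within-month convention); an any-visit variant is available
(`rule="any"`). The local-regression smoother (tricube-weighted local
linear fit, span 0.6) is presentation-only and excluded from any
quantitative claim.

## Seasonal growth model

For a z-score response (WLZ by default),

    z_ij = f(age_ij) + Σ_{k=1,2} [α_k sin(2πk t_ij/P) + β_k cos(2πk t_ij/P)]
           + age_ij [γ_s sin(2π t_ij/P) + γ_c cos(2π t_ij/P)]
           + u0_i + u1_i age_ij + a_i sin(2π t_ij/P) + b_i cos(2π t_ij/P) + e_ij

with `t` = day-of-year and period `P = 365.25` days fixed. `f` is a
natural cubic spline in age (months), boundary knots at 0 and 24 months,
interior knots at the 25/50/75 age percentiles of the data (configurable);
the basis is the truncated-power natural-spline construction, linear
beyond the boundaries, and is verified in the tests to reproduce an
arbitrary natural cubic spline through the same knots to < 1e−8. The
age-dependence of the seasonal swing is modelled parsimoniously as
linear-age × annual harmonic. Random effects per child — intercept, age
slope and the annual pair (a_i, b_i) — have an unstructured 4×4
covariance; residuals are i.i.d.

Estimation is REML via statsmodels `MixedLM`. The optimizer ladder is
BFGS → L-BFGS → Powell → diagonal-covariance BFGS → diagonal Powell; the
method actually used and any fallback are recorded in the fit. The
derivative-free Powell step matters when a variance component sits on the
boundary (e.g. a response with no individual seasonal variation), where
gradient methods stall. Non-convergence of the whole ladder raises an
explicit failure carrying the attempt diagnostics.

The **CCV** of a child is defined as the amplitude `√(a_i² + b_i²)` of
their (shrunken, BLUP) annual pair, in z-score units: the child's own
seasonal swing above or below the mean curve's swing. Amplitude rather
than an amplitude/mean ratio is used because z-scores cross zero, making
any mean-normalised version unstable; the definition is isolated in
`compute_ccv` so an alternative can be swapped in. Population trajectories
for a given birth date set the random effects to zero and carry the birth
date's seasonal imprint through day-of-year.

Sexes are fitted separately at the pipeline level (`growth_by_sex`); the
stratified-by-outcome fits skip strata under 10 subjects with a warning.

## Risk models

Logistic regressions are maximum likelihood (statsmodels `Logit`) with
Wald 95% CIs on the odds-ratio scale (profile likelihood was considered
and rejected as unnecessary at these sample sizes). Complete separation is
detected — fitted probabilities of the two outcome classes strictly
disjoint, or statsmodels' own separation signal — and raised as an error
naming the term dominating the linear-predictor spread; a raw
coefficient-magnitude heuristic was rejected because legitimately huge
coefficients arise on tiny-scale features (a random-slope feature has SD
~0.02, so its OR per unit is extreme by construction). Constant predictor
columns are dropped with a warning.

The stunting-at-20–24-months models are nested — I: sex + ever stunted
before 20 months; II: + ever wasted; III: + random-effect features
(intercept, slope, CCV) — and fitted on a common complete-case row set so
their log-likelihoods are comparable. Ever-flags derive from the monthly
classifications at completed months 0–19, keeping one canonical
classification pathway. Classification diagnostics (error %, FNR % among
observed positives, FPR % among observed negatives) classify at predicted
probability ≥ 0.5 by default (threshold configurable, in-sample by
design).

## Time-lagged multilevel model

Each visit is matched to the same child's earlier visit minimising
|lag − 3 months| among candidates with lag in [2.5, 3.5] months
(months of 30.4375 days); current visits with no candidate are dropped; a
prior visit may serve several current visits. An exactly equidistant tie
prefers the longer lag — unreachable from integer-day dates (2 × 3 ×
30.4375 days is not a whole number of days) but defined and tested for
float inputs. Matching is at the visit level (flags from that visit's
z-scores), since the window is defined in days, not month-bins.

The model is a logistic regression of the current state (stunted; or
wasted for the reciprocal model) on intercept, sex (boy = 1), lagged age
(months, continuous), lagged stunted and lagged wasted, with a Gaussian
random intercept per child and no interactions. The marginal likelihood
integrates the random intercept by 25-node Gauss–Hermite quadrature and is
maximised by L-BFGS-B with the intercept SD bounded at zero, so a
degenerate fit collapses exactly onto plain logistic regression (verified
to 2 decimals in the tests). Standard errors are Wald from the numerical
Hessian; with the SD on the boundary the Hessian is taken over the fixed
effects alone. A failed optimisation retries with 50 nodes before raising.
The intercept SD itself is weakly identified in sticky low-prevalence
chains (the lagged state absorbs most persistence) and should be read as a
nuisance parameter; the fixed effects are what the model is for.

Scenario probabilities are evaluated at random intercept 0 (the median
child) over the four lagged-state groups (neither / stunted only / wasted
only / both) × sex × lagged-age grid.

## Synthetic cohort generator

The generator is the package's stand-in for undeposited clinic data and
defines the default study condition; all of its draws flow from one seed
and the output is bit-reproducible.

**Schedule.** Births uniform over 1990–1993 (spreading birthdays across
the seasonal cycle); visits at birth, 6 weeks, 3 months, then 3-monthly to
24 months; per-visit attendance 0.85 (birth always recorded); date jitter
N(0, 7 d) truncated at ±21 d. Median visits per child ≈ 9.

**Continuous outcomes.** WLZ = mean age curve (monotone-cubic through
(0, −1.0), (3, −0.35), (12, −0.95), (24, −0.7) — early catch-up, a dip
toward one year) + seasonal forcing `0.4 · s(age) · cos(2π(doy − 46)/365.25)`
(peak mid-February, trough mid-August in the wet season;
`s(age) = min((age+3)/9, 1)` ramps seasonal vulnerability in over infancy,
switchable off for amplitude-recovery runs) + per-child random intercept
(SD 0.6), age slope (SD 0.02/mo) and annual pair (SD 0.4 per component) +
residual N(0, 0.5). LAZ declines linearly from −0.4 at birth to −1.6 at
24 months around per-child intercept (SD 0.9, correlation 0.4 with the
WLZ intercept — shared frailty) and slope (SD 0.02/mo), plus a mild
seasonal term (amplitude 0.15) trailing the WLZ cycle by 90 days (length
responds later than weight), residual N(0, 0.45). Boys sit 0.10/0.15 z
lower in WLZ/LAZ. The lagged wasting → stunting coupling is dynamic: each
wasted visit adds 0.4 z to a LAZ deficit that decays by factor 0.85 per 3
months. These values were fixed once to make the default condition
"study-like" — wasting prevalence peaking in the 10–20% band near one
year, stunting rising to ~35–50% by 24 months, and recoverable coupling —
and are not tuned per test.

Raw lengths and weights are back-computed from the realised z-scores
through the bundled LMS reference (z-score inversion), so the scoring
module is exercised end to end; re-scoring recovers the planted z's up to
the 0.01 cm / 0.001 kg rounding of the raw values (< 0.02 z).

**Planted corruption.** At rate `r`, half the planted records get an
impossible z (|LAZ| ∈ 6.5–7.5 or |WLZ| ∈ 5.5–6.5, sign chosen to keep raw
values inside the reference grids) and half get a single-visit WLZ spike
of 3.8–5.2 SD (never the first visit, one per child, clipped inside the
plausible band). Implausible plants are recalled at exactly 100% by
construction (the corruption survives re-scoring); spikes are recalled at
≥ 95% pooled over seeds — a spike can hide when the child's neighbouring
visits drift toward it, which is intentional realism.

**Binary panel.** A second, deliberately separate pathway simulates
(stunted, wasted) chains at 3-month waves from exactly the lagged
random-intercept logistic transition model (default log-odds: baselines
ln 0.012 / ln 0.013, sex ln 1.6 / ln 1.5, age ln 1.1 / 0, lagged stunting
ln 8.2 / ln 1.5, lagged wasting ln 3.2 / ln 2.9, intercept SD 0.5;
initial states independent of the intercepts, so the transition likelihood
is correctly specified). It exists for coefficient recovery and CI
calibration and is not forced to be mutually consistent with the
continuous pathway.

**What the generator does not emulate:** mortality/migration, secular
trends over decades, measurement digit preference, seasonal variation in
attendance, MUAC dynamics beyond a crude WLZ-linked curve. Passing tests
therefore demonstrate that the estimators recover the structure they
assume when it is present at realistic strength and noise — not that real
clinic data satisfy those assumptions.

## Problem sizes and measured behaviour

The test suite and acceptance script use cohorts of 150–1000 children
(panels to 4000), chosen to make every stochastic check comfortably
repeatable: seasonal fixed-amplitude recovery lands within ~4–8% of truth
(15% tolerated) at n = 1000 × ~9 visits; the Spearman correlation between
true per-child amplitude and estimated CCV runs ≈ 0.65 at those sizes;
lagged-model fixed effects recover within ±0.17 log-odds at n = 4000
(±0.3 tolerated); per-term 95% CI coverage under a null coupling measures
92% over 50 seeds at n = 1000. Directional study-structure checks
(wasted-group excess stunting after 3 months, wet-season-birth WLZ
deficit, ever-wasted OR > 1, lagged-wasting OR > 1) hold in ≥ 90% of seeds
at n = 800.

## Known limitations

- Wald CIs mildly undercover for rare-event terms at n = 1000 (null
  z-statistic SD ≈ 1.26 for the lagged-wasting term); profile-likelihood
  intervals would help at small sizes.
- The quadrature is non-adaptive Gauss–Hermite; with very large cluster
  sizes or intercept SDs ≫ 1 an adaptive rule would be safer.
- Duplicating every row of a mixed-model frame does *not* leave fixed
  effects unchanged (it shifts the residual-vs-random variance balance);
  only exact refit determinism is guaranteed.
- The random-intercept SD of the lagged model is weakly identified in
  sticky low-prevalence chains (see above).
- The toy LMS reference is synthetic; absolute prevalence levels computed
  against it are internally consistent but not comparable to WHO-standard
  numbers.
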