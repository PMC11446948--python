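# Methods

## Study design and cohort

The analysis follows individuals from 3 years before to 5 years after a
clinical diagnosis of type 2 diabetes, on a diagnosis-relative time axis
(years of 365.25 days).  Three periods are distinguished:

* **pre-diagnosis**, t ∈ [−3, −0.5] years — modelled;
* **peri-diagnosis**, t ∈ (−0.5, 1) years — *never* modelled, because the
  period around diagnosis shows an abrupt weight disturbance that a linear
  trajectory cannot represent; it is summarised by the simple annualised
  rate (BMI₁ − BMI₋₀.₅)/Δt;
* **post-diagnosis**, t ∈ [1, 5] years — modelled with time-varying
  exposure adjustment.

Eligibility requires four anchor measurements (the observation closest to
the target inside a closed window): BMI₋₃ (target −3, window [−3, −2]),
BMI₋₀.₅ (−0.5, [−1.5, −0.5]), BMI₁ (1, [1, 2]), BMI₅ (5, [4, 5]); plus
diagnosis at age ≥ 35 inside the calendar range 2003–2014, BMI₁ ≥ 25 kg/m²
and at least one HbA1c in [1, 2) years.  Filters run sequentially and each
excluded individual is logged against the first failing filter, so the
exclusion log sums to the total excluded.

Conventions the source design leaves open, fixed here once:

* anchor windows are closed at both ends; the HbA1c eligibility window is
  [1, 2) so that year-bins stay disjoint;
* an exact anchor tie (two in-window observations equidistant from the
  target) resolves to the *earlier* observation (deterministic, favours a
  longer modelled span);
* age is continuous, (diagnosis − birth)/365.25, banded without flooring;
* missing deprivation is kept as its own level rather than imputed or
  dropped;
* the pre-diagnosis model uses **all** BMI observations in [−3, −0.5], not
  only the two anchors (the anchors are an eligibility device; typical
  eligible individuals contribute 3–5 pre-diagnosis measurements);
* the pre-diagnosis calendar bands (<2006, 2006–07, 2008–09, 2010–11) are
  not exhaustive for diagnoses through 2014, so the last band is
  implemented open-ended (">=2010").

## Exposure coding

Drug classes: metformin, sulfonylurea, thiazolidinedione, DPP4i, GLP-1RA,
SGLT2i, insulin.  A dispensing episode covers [start, end + grace] with
`grace_days = 0` by default (episodes are taken at face value; a grace
period is a config switch for real-world dispensing dialects, not an
analysis assumption).  The active class set at an observation date maps to
a regimen label: any insulin ⇒ `insulin_any`; none ⇒ `none` (the
reference, "before medications were started"); otherwise
`mono:<class>`, `dual:<a+b>`, `triple:<a+b+c>` with classes sorted
alphabetically so each combination has one spelling; ≥ 4 non-insulin
classes pool into `quad_plus`.  Regimen levels with fewer than
`min_regimen_obs = 30` observations are pooled into `other` before
fitting.

HbA1c change is the percentage change from the individual's *baseline*
(first measurement at t ≥ 1), in five categories: `no_change` (exactly 0,
reference), `dec_0_10` (0 < decrease < 10%), `dec_ge10` (≥ 10% decrease),
`inc_0_10`, `inc_ge10`; the ±10% boundaries belong to the ≥10%
categories and zero belongs to the reference.  Each BMI observation pairs
with the most recent HbA1c at or before its date (carry-forward — the
causally ordered choice), falling back to the nearest within
`pairing_window_days = 90`; unpairable observations carry the reference
category and a flag.  Carry-forward, not interpolation, is the only rule
implemented.

## The mixed model

For individual *i* at times t_i1..t_in:

y_i = X_i β + Z_i b_i + e_i,  b_i ~ N(0, G),  e_i ~ N(0, σ² R_i),
Z_i = [1, t_i],  R_i[j,k] = ρ^|t_ij − t_ik|.

The spatial-power correlation is the continuous-time analogue of AR(1):
equally spaced data reduce to AR(1) with lag-1 correlation ρ.  Because
ρ^d with real gaps d is undefined for ρ < 0, ρ is constrained to [0, 1)
(negative serial correlation is outside the family; clinic BMI noise is
positively correlated in practice).

**Estimation.**  REML, maximised over an unconstrained parameterisation:
log-Cholesky factors of G̃ = G/σ² (3 parameters) and a logistic transform
of ρ.  β is profiled out by generalised least squares and σ² in closed
form, so the optimiser (L-BFGS-B, numerical gradients, two fixed starts,
objective tolerance 1e-10, Nelder-Mead polish if line search aborts on a
degenerate surface) works in ≤ 4 dimensions.  All linear algebra is
per-individual and batched (padded arrays, vectorised Cholesky/solve);
the full-cohort covariance is never materialised.  Wald 95% CIs use
normal quantiles from cov(β̂) = σ̂²(X'W⁻¹X)⁻¹; no small-sample
(Satterthwaite/Kenward–Roger) correction is applied — a documented
limitation for small cohorts.  Duplicate times within an individual are
perturbed by one day to keep R_i positive definite, and collinear fixed
columns are pruned (recorded on the design).

**Outliers.**  After the base fit, observations with internally
studentised marginal residual |y − x'β̂| / √(diag V̂_i) > 3 are removed
and the model refitted exactly once (not iterated).  Individuals left
with no observations are dropped and recorded.  Under normality ~0.27% of
clean observations are flagged.

**Trajectories.**  Individual annual rates are β̂_time + b̂_i1 (fixed
slope plus BLUP slope deviation), then classified into 7 categories:
stable = [−0.1, 0.1], slow = (0.1, 0.3], moderate = (0.3, 0.5], rapid =
(0.5, ∞) kg/m²/year in absolute value, signed loss/gain — one consistent
half-open convention, verified by boundary sweeps.  Trajectories are only
defined for the base specification (intercept + time, plus exposure
offsets post-diagnosis); a fit containing covariate×time interactions has
no single population slope and is refused.  Note that BLUPs shrink toward
the population slope, so the cross-individual spread of estimated
trajectories understates the latent slope spread — strongly so when
individuals contribute few measurements (pre-diagnosis: typically 3–5).

## Covariate models

Each covariate (sex; age band <50/50–<60/60–<70/≥70; BMI band; deprivation
quintile incl. missing; calendar band; post-diagnosis also HbA1c band,
pre-diagnosis trajectory category and peri-diagnosis change category)
enters as main effect plus covariate×time interaction; the interaction
coefficient is the difference in annual slope versus the reference level.
Strategy: univariable models first; the multivariable model contains every
covariate with any interaction p < 0.05 (no multiple-testing correction —
none is applied anywhere, stated plainly) plus always-retained confounders
(default age band and sex, configurable).  The outlier pass runs once on
the base model and all covariate models reuse the cleaned rows, so every
model of an analysis uses identical observations.  The post-diagnosis
covariate models keep the regimen and HbA1c-change offsets in the fixed
part throughout.

## The synthetic-EMR generator

The generator adopts the analysis model so that recovery is a meaningful
test: latent piecewise-linear BMI per individual (knots at −0.5 and +1
years; the latent value at t = +1 anchors the line), plus the regimen
offset active at t, plus the HbA1c-category offset at t — coded with
exactly the analysis rules — plus Gaussian errors with corr = ρ^|Δt|.
Visits are a thinned Poisson process; HbA1c is an individual random walk
whose drift turns negative under treatment (so HbA1c change and treatment
are realistically entangled); dispensing follows simple
scenario scripts (diet-only, metformin monotherapy, other monotherapies,
insulin-with-metformin, metformin-based dual therapies) with persistent
episodes.  Dates are emitted at 365.25 days/year and whole-day resolution.

Defaults describe the emulated conditions: diagnosis years 2003–2014; age
at diagnosis N(65.6, 10.1²) floored at 35; 43% female; deprivation
probabilities (0.21, 0.23, 0.19, 0.17, 0.20) with 2% missing; latent
1-year BMI N(33, 5.9²) floored at 25; slopes (mean, SD) in kg/m²/year —
pre (0.25, 0.50), peri (−0.25, 0.75), post (−0.14, 0.45); banded slope
shifts (e.g. +0.38 for age <50 pre-diagnosis); drug offsets in kg/m²
(metformin −0.32, sulfonylurea +0.31, thiazolidinedione +1.22, insulin
+0.29, metformin+SGLT2i −1.04, metformin+GLP-1RA −0.79, metformin+DPP4i
−0.39); HbA1c-category offsets (−0.43 for ≥10% decrease, +0.48 for ≥10%
increase, ±0.15 for the 0–10% bands); residual SD 0.8 kg/m², ρ = 0.5;
BMI visit rate 1.7/year and HbA1c rate 2.0/year with 10% missingness.
The single visit rate is a compromise calibrated to give roughly 4
pre-diagnosis and 6–7 post-diagnosis measurements per eligible
individual; it is not calibrated further.  Under these defaults roughly
30% of simulated individuals pass all filters — the anchor requirement
dominates, as it does with real EMR coverage.

What the generator does **not** emulate: realistic prescribing sequences
or switching, dose and adherence, visit processes correlated with health
state (informative observation), non-Gaussian measurement error, missing
BMI dependent on BMI, comorbidity, or any peri→post dependence beyond
independent slope draws.  Passing recovery tests therefore shows the
estimation machinery is correct under the stated model, not that the model
is correct for any particular real population.

## Validation harnesses and problem sizes

* Likelihood oracle: block-diagonal REML vs a dense whole-cohort matrix
  evaluation (independent code path), 15 subjects, agreement to 1e-8
  relative.
* Reduction oracle: ρ = 0 fit vs statsmodels MixedLM (REML, same
  specification), 200 subjects, shared parameters within 1e-3.
* Variance components: 20 replicates at 500 individuals (ρ = 0.5, σ = 1,
  slope SD 0.3, intercept SD 3, ~6 visits over 4 years); replicate means
  within 2 Monte-Carlo SE of truth.
* Exposure offsets: 6 replicated end-to-end runs at 2000 simulated
  individuals; the Monte-Carlo SE is the replicate SD / √6 because the
  model-based SE understates replicate variability (the exposure
  contrasts are sensitive to the estimated covariance parameters, whose
  REML surface is flat in ρ on some realizations).
* Covariate×time interaction: +0.38 kg/m²/year planted on the 60–<70 age
  band (the best-populated non-reference band under the default age
  distribution), 6 replicates at 3000 individuals, mean recovered within
  ±0.05.
* Outlier machinery: clean flag rate in [0, 1]%, ≥90% of 2% gross
  contamination (10 marginal SDs) removed, threshold = ∞ a no-op.
* Determinism: two CLI `all` runs with one seed produce byte-identical
  tables and checksums.

These sizes keep the full suite and the acceptance script each within a
few minutes on one CPU.

## Known limitations

* ρ ≥ 0 only (inherent to the power form at fractional lags).
* One grouping level, Gaussian response, no crossed random effects, no
  robust/sandwich errors.
* Individual trajectories come from the base model only; deriving them
  from covariate models is ambiguous (the fixed slope becomes
  covariate-dependent) and is deliberately refused.
* The multivariable selection rule (p < 0.05 univariable + forced
  confounders) is a convention; the retained set is exposed in config
  rather than inferred.
* Wald intervals without small-sample correction.
* Simulated visit processes are non-informative; real EMR measurement is
  not.
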