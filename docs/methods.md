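# Methods

`echorisk` implements, end to end, the construction and internal validation
of a pre-operative risk score for peri-operative cardiorespiratory adverse
events in children with idiopathic pulmonary arterial hypertension (PAH)
undergoing elective cardiac catheterization under general anesthesia. The
predictors are seven routine trans-thoracic echocardiography measures plus
age; the outcome is a composite of complications (arrhythmia, cardiac
arrest, pulmonary hypertensive crisis, hypotension forcing termination,
broncho-/laryngospasm, difficult intubation, death) and unforeseen
escalations of care (new intravenous or inhaled vasoactive therapy, failed
extubation or reintubation, post-operative ventilatory support, unplanned
ICU admission) within 24 h of induction.

Because no patient-level data are distributed, the package ships a
synthetic-cohort generator that reproduces the cohort's statistical
structure; every statistical claim made by the test suite is a claim about
the method's behaviour under those simulated conditions, not a re-analysis
of patient data.

## Data model and encodings

Qualitative echo severities use a seven-level ordinal Likert scale:

| label | none | trivial | mild | mild/mod | moderate | mod/severe | severe |
|---|---|---|---|---|---|---|---|
| value | 0 | 0.25 | 1 | 1.5 | 2 | 2.5 | 3 |

Half-grades sit at the midpoints of their neighbours and *trivial* sits
near *none*, mirroring the common pooling of none/trivial in baseline
tables. The exact spacing is a design choice; it is irrelevant to the
category-based score (which only needs the band boundaries) and only mildly
affects the screening step, where grades enter as standardized values.

Derived quantities: pulmonary vascular resistance PVR = (mPAP − PCWP)/CO in
Wood units; intra-operative hemodynamics may be expressed as percent change
from admission, 100·(intra − admission)/admission. The composite adverse
flag is the OR of the complication and escalation flags, each set by the
presence of at least one event from the respective controlled vocabulary
(synonyms normalized at read time).

## Synthetic cohorts

One patient-level latent severity factor f ~ N(0,1) drives the echo
measures: each ordinal grade thresholds λ·f + √(1−λ²)·ε at fixed cut
points chosen so that most catheterizations show none-to-mild disease;
velocities are linear in the factor with observed-scale moments
(TR Vmax 4.1 ± 1.0 m/s, PR Vmax 2.8 ± 1.0 m/s, PR end-diastolic velocity
2.5 ± 0.7 m/s). The two pulmonary-regurgitation velocities additionally
share a residual correlation calibrated so their total correlation hits a
configurable target, 0.68 by default. Loadings (0.5–0.8) were chosen once
to reproduce the reported 0.5–0.6 correlations between echo pressure
surrogates and invasive mPAP. Age is truncated-normal (8.8 ± 4.6 y on
0.2–18 y), independent of the factor, drifting upward slightly across a
patient's repeat catheterizations.

Patients contribute 1 + Poisson(0.7) catheterizations (≈1.7 on average,
matching 158 catheterizations from 93 children); the per-patient count
distribution is otherwise unreported, so the truncated Poisson is a
stand-in. Outcomes follow

  logit P(adverse) = α + Σ_v β_v·x̃_v + u_patient,  u ~ N(0, σ_u²)

with standardized predictors, default log-odds ratios of 0.7–0.9 per SD
for the echo measures and −0.8 per SD for age (younger = riskier), and
σ_u = 1 by default. α is calibrated by Monte-Carlo (200,000 draws from a
private, config-keyed stream) so the marginal event rate equals the target
prevalence (default 10%) to within ±0.005. Everything downstream of a
`(config, seed)` pair is bit-reproducible.

What the generator does **not** emulate: informative missingness, secular
drift in practice, measurement error correlated with disease severity,
anesthetic-course covariates, and competing risks between individual event
types. Passing tests therefore demonstrate correctness and calibration of
the *procedures*, not clinical performance on real patients.

## Univariate screening

Each candidate predictor is screened with a Bayesian mixed-effects logistic
model (random intercept per patient), the random effects integrated out by
15-point Gauss-Hermite quadrature, leaving a 3-parameter marginal posterior
over (intercept, slope, log σ_u). Priors are weakly informative —
Normal(0, 2.5²) on the standardized coefficient, Normal(0, 10²) on the
intercept, Half-Normal(1) on σ_u — and deliberately configurable: the
original priors are not published, so a prior-sensitivity analysis
(refitting under several prior widths and reporting the maximum coefficient
shift) is a first-class operation rather than an afterthought.

Two posterior approximations are available. The Laplace path (MAP +
normal approximation from the numerical Hessian) is deterministic and runs
in milliseconds, which makes the replicated simulation studies (type-I
calibration at 500 cohorts, power curves) affordable; the MCMC path runs
independent affine-invariant ensembles (emcee, differential-evolution
moves, initialized at the MAP) and reports split-R̂ across ensembles with a
1.01 convergence bar. The two agree closely on the cohort sizes used here;
tests pin their agreement.

"Significant" is operationalized as the two-sided posterior tail
probability p_B = 2·min(P(β>0), P(β<0)) < 0.05, equivalently the 95%
credible interval excluding zero — the usual Bayesian reading of a p < 0.05
screen. Selected predictors then pass a collinearity filter: for each pair
with |Pearson r| ≥ 0.6 (pairwise-complete), processed in descending |r|,
the variable with the weaker posterior evidence is discarded — on default
synthetic cohorts this reliably removes one of the two
pulmonary-regurgitation velocities, whichever screens weaker in that draw.

Power by simulation: the fraction of synthetic cohorts (Clopper-Pearson
interval) in which the screen selects a predictor carrying a specified
log-OR, at configurable cohort size and prevalence.

## Score construction

Kept predictors are binned into low/medium/high risk categories with closed
middle intervals: age > 7 y / 3–7 y / < 3 y (risk decreasing with age),
velocities < 3.0 / 3.0–5.0 / > 5.0 m/s, qualitative grades none–mild /
mild-moderate–moderate / moderate-severe–severe. Boundary values (age
exactly 3 or 7; velocity exactly 3.0 or 5.0) land in the medium band.

Categories are coded linearly 0/1/2 and a one-component PLS1 regression
(NIPALS, implemented in-repo and cross-checked against
scikit-learn) of the outcome on the codes is fitted on each of B = 1000
bootstrap resamples (rows by default; an optional cluster bootstrap
resamples patients). Per-variable **median** bootstrap coefficients β_v are
rescaled to points: points_v(c) = c·100·β_v / (2·Σ_v β_v), so an all-low
record scores exactly 0, all-medium 50, all-high 100. The linear 0/1/2
coding is what makes the all-medium anchor land exactly at the midpoint.
Zero-sum per-variable display offsets are supported (the published table
distributes non-zero low-risk points that sum to zero across variables; the
generating rule for that distribution is unpublished, so the default is
zero offsets) — offsets change no total. Negative median coefficients can
arise on noise and are clipped to zero (the variable then contributes no
points); if *all* coefficients are non-positive there is no risk-increasing
signal and the rescaling refuses.

The "pragmatic" step rounds the point values to integers over the unified
boundaries above; rounding can perturb each anchor sum by at most half a
point per variable (≤ 3.5 for seven variables), and the deviation is
reported. The published seven-variable table is shipped verbatim as a
hard-coded reference system whose columns sum to exactly 0/50/100; it is a
constant, never re-derived.

Inference on the finished score is by permutation: the observed ROC AUC is
compared with the AUCs obtained by permuting outcome labels across
catheterizations, p = (1 + #{AUC_perm ≥ AUC_obs})/(B + 1) (add-one
estimator, so p is never 0).

## Evaluation and internal validation

ROC AUC is the tie-corrected Mann-Whitney probability; an explicit
trapezoidal integration is kept as an independent equal-by-theorem route
and the two are pinned to 10⁻¹² agreement in tests. PR AUC is average
precision with tied scores grouped, chosen over interpolated variants
because it makes the no-skill baseline equal the outcome prevalence
exactly. Resampling intervals are percentile bootstrap over records
(resamples that lose an outcome class are redrawn, at most 10 times each).

Optimism correction follows Harrell's bootstrap and treats the *entire*
development pipeline (binning → bootstrap-PLS → rescaling) as the unit
being validated: for each of B bootstrap cohorts the pipeline is refitted
from scratch, optimism is the mean of (performance on the bootstrap cohort
− performance of that refit on the original cohort), and the corrected
value is apparent − optimism. Refitting only the final regression would
understate optimism. Both ROC and PR AUC can be corrected.

## Post-hoc models

Risk curves per outcome (complication, escalation, no adverse event; the
first two may overlap, and an exclusive coding is available) are Bayesian
logistic fits of each indicator on the score, with the same weakly
informative priors; predicted-risk bands are pointwise 95% credible
intervals from a Laplace approximation, reported only over the observed
score range. The score-outcome association is confirmed with the same
mixed-effects machinery used for screening (score standardized, patient
random intercept). Covariate checks (e.g. balloon atrial septostomy) report
odds ratios for binary covariates and flag perfect separation, which the
prior keeps finite.

Group comparisons of scores use the two-sided Wilcoxon rank-sum statistic
with tie correction and continuity correction; for combined samples of
12 or fewer the p-value switches to the exhaustive permutation distribution
of the rank sum, because the normal approximation is not trustworthy there
(for 2 vs 2 it can miss the exact p by ~0.09). Medians and IQRs accompany
every comparison.

## Numerical choices and problem sizes

- Gauss-Hermite order 15 (adequate for σ_u ≲ 2; configurable).
- Laplace Hessians by central differences (step 1e-4), ridged on failure.
- MCMC default budget: 4 independent ensembles × 8 walkers, 2000 post-warmup
  draws per ensemble; split-R̂ < 1.01 expected, warned otherwise.
- NIPALS tolerance 1e-12; rank-deficient components terminate the loop.
- Replicated simulation studies in the test suite run the Laplace path at
  the study's own size (93 patients, ~158 catheterizations): 500 null
  cohorts for the type-I check, 200 for parameter recovery, 150 per grid
  point for power curves, 50 runs × B = 200 refits for the overfitting
  check. These sizes are the package's chosen compromise between
  Monte-Carlo error and convenience; they are easily raised in the calls.
- Bootstrap/permutation defaults: B = 1000 (PLS), 999 (permutation),
  2000 (percentile CIs), 200 (optimism).

## Known limitations

- The "optimized" (unrounded, per-variable-boundary) system of the source
  study is unpublished; the procedure that would produce it is implemented,
  but its specific fitted values are not claimed or reproduced.
- The Laplace path reports a symmetric interval; for very sparse outcomes
  (few events) the posterior is skewed and the MCMC path is preferable.
- The generator's latent structure is a modelling convenience; rank
  correlations between echo measures are reproduced only approximately.
- Bootstrap resampling of repeated measures ignores within-patient
  correlation unless the cluster (patient) resampling option is chosen.
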