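# echorisk

Pre-operative echocardiographic risk scoring for children with idiopathic
pulmonary arterial hypertension (PAH) undergoing elective cardiac
catheterization under general anesthesia.

Children with idiopathic PAH face some of the highest peri-operative risks
in pediatric anesthesia. Cardiac catheterization is the diagnostic
gold standard, but echocardiography is non-invasive, widely available, and
measurable without anesthesia — which makes an echo-based pre-operative
risk score clinically attractive for consent discussions and care
planning. `echorisk` implements the full development and internal-validation
machinery for such a score, together with the published seven-variable
0–100 point "pragmatic" scoring table, for biostatisticians and clinical
researchers who want to reproduce, stress-test, or extend the approach.

## What it implements

- **Cohort data model and I/O** — one row per catheterization, repeated
  measures per patient; ordinal echo severities on a 7-level Likert scale;
  derived hemodynamics (PVR = (mPAP − PCWP)/CO); a composite adverse-event
  outcome (complications OR unforeseen escalations of care). Format
  dictionary in `docs/cohort_file_format.md`.
- **Synthetic cohorts** — a generator reproducing the study conditions
  (93 patients, ~1.7 catheterizations each, 10% adverse-event prevalence,
  a patient-level latent severity factor, r ≈ 0.68 between the two
  pulmonary-regurgitation velocities, patient random intercepts), with the
  logistic intercept calibrated by Monte-Carlo to hit the target
  prevalence. No download required; everything is testable offline.
- **Screening** — Bayesian univariate mixed-effects logistic regression
  (random intercept per patient, Gauss-Hermite marginalization; Laplace and
  ensemble-MCMC posteriors), selection by the 95% credible interval
  excluding zero, collinearity filtering, prior-sensitivity analysis, and
  power-by-simulation.
- **Score construction** — low/medium/high binning, one-component PLS
  (NIPALS, in-repo) on 1000 bootstrap resamples, median coefficients
  rescaled so all-low/all-medium/all-high records score exactly
  0/50/100 points, integer rounding, and permutation inference.
- **Evaluation** — ROC AUC (tie-corrected Mann-Whitney) and
  precision-recall AUC (average precision; no-skill baseline = prevalence),
  percentile-bootstrap intervals, and Harrell bootstrap optimism correction
  that refits the *entire* development pipeline per resample.
- **Outcome models** — per-outcome Bayesian logistic risk curves over the
  observed score range, mixed-effects confirmation, covariate checks
  (odds ratios, separation detection), Wilcoxon rank-sum group comparisons
  (exact for small samples).

The core scoring rule, for the published table: each of seven variables
(age; RV dysfunction; RV dilatation; TR severity; TR velocity; PR severity;
PR velocity) falls in a low/medium/high band — age > 7 / 3–7 / < 3 years,
velocities < 3.0 / 3.0–5.0 / > 5.0 m/s, grades none–mild /
mild-moderate–moderate / moderate-severe–severe — and contributes fixed
points; the three column sums are exactly 0, 50 and 100.

## Worked example

```python
import echorisk as er

cohort = er.simulate_cohort(er.SimConfig(), seed=1)
dev = er.develop_score(cohort, B_pls=1000, seed=1)
print([s.variable for s in dev.kept])
print(dev.pragmatic_system.anchor_sums())
print(round(dev.auc_roc, 3), dev.permutation_p)
```

prints (with these seeds):

```
['rv_dysfunction', 'rv_dilatation', 'tr_severity', 'tr_vmax', 'pr_severity', 'pr_edv']
(0.0, 51.0, 100.0)
0.972 0.001
```

Six of the eight candidates survived screening and the collinearity filter
(in this draw, pulmonary end-diastolic velocity screened stronger than PR
Vmax and displaced it at r = 0.64); after integer rounding the anchor sums
drift by at most half a point per variable (51 vs 50 here); the developed
score separates event from event-free catheterizations with apparent
ROC AUC 0.97, and no label permutation matched it (p = 1/1000). Scoring a
single echocardiogram against the published table:

```python
from echorisk import EchoExam, SeverityGrade, pragmatic_total
exam = EchoExam(
    age_years=5.0,
    rv_dysfunction=SeverityGrade.from_label("moderate"),
    rv_dilatation=SeverityGrade.from_label("mild"),
    tr_severity=SeverityGrade.from_label("moderate"),
    tr_vmax=4.2,
    pr_severity=SeverityGrade.from_label("mild"),
    pr_vmax=2.5,
)
pragmatic_total(exam)   # -> 25.0  (-13 + 14 + 3 + 5 + 9 + 7 + 0)
```

The same workflow is available as numbered drivers
(`analysis/01_simulate_cohort.py` … `05_outcome_models.py`, each writing
its tables under `results/`) and as a CLI
(`echorisk simulate|screen|develop|score|evaluate|report|run`).

## Scope

The package does not process echo images or MRI flow data (measurements
arrive as numbers/labels), performs no external validation, and ships no
clinical decision thresholds. Simulated cohorts emulate the statistical
structure of the study conditions, not real patients; see
`docs/methods.md` for the model, assumptions, parameter defaults and
limitations.
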