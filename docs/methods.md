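# Methods

## Model and procedure

The package treats weaning-readiness testing as a diagnostic-test problem:
a scalar index computed from a single pre-SBT ventilator/blood-gas
measurement is used to predict the binary outcome of a 30-minute
spontaneous breathing trial, with trial failure as the positive class.

All indices derive from four primitives measured under pressure-controlled
ventilation (P_max, PEEP, V_T, RR) plus the pre-trial PaCO₂ and
demographics. Mechanical power uses the simplified pressure-controlled form
MP = 0.098·RR·V_T·P_max, with the conversion constant fixed at exactly
0.098 J/(cmH₂O·L) — not the more precise 0.0980665 — so that the
compliance-normalized index collapses algebraically:
LTC_dyn-MP = MP / (0.098·LTC_dyn/1000) = RR·P_max·ΔP_aw with no residual
unit factor. This identity is enforced to 1e-9 relative tolerance in the
tests and is the main internal-consistency check of the index layer.
Predicted body weight uses the standard height/gender formula
(50 or 45.5 + 0.91·(height − 152.4 cm)). The Power index exponent k on
(PaCO₂/45)^k is an explicit parameter with the two study values 1.0 and
2.0 computed side by side; 45 mmHg is the isocapnic target. Tidal volume is
accepted in mL at the record boundary and converted to litres once inside
the power formula; a value above 3 L triggers a unit-confusion warning.

Outcome classification uses strict inequalities at every cut-off
(BF > 35/min, HR > 130 bpm, SBP > 160 mmHg, SpO₂ < 88 %, PaCO₂ > 45 mmHg).
pH is recorded but never an independent failure trigger: acidosis
accompanies hypercapnia rather than defining failure on its own. A missing
post-trial blood gas is allowed as long as at least one decision field is
present.

## Synthetic cohort generator

Real patient data are unavailable, so cohorts are simulated with the
published two-group structure: 100 successes and 30 failures by default.
Primitives are drawn per group from truncated normals at the published
means ± SD (truncation at mean ± 3 SD, tightened by physiologic bounds:
FiO₂ in [0.21, 0.40], PEEP in [3, 8] cmH₂O per the trial screening
criteria), and P_max is redrawn until it exceeds PEEP + 2 cmH₂O. Indices
are never stored — they are always recomputed from primitives — so the
algebraic identities hold on generated data exactly as on real records.

Respiratory rate is not published directly; its group parameters
(16.5 ± 2.7 success, 16.5 ± 2.0 failure breaths/min) are back-derived from
the published minute-ventilation (9.0 ± 2.0 / 9.0 ± 1.7 L/min) and
tidal-volume moments under within-group independence, since
MV = RR·V_T/1000. Height is likewise not published; it is drawn
N(175, 7²) cm for men and N(165, 7²) for women, and body mass follows from
a per-group BMI draw (26.5 ± 5 success, 29 ± 6 failure, consistent with the
published medians). The BMI draw is conditioned on the Bernoulli obesity
flag (prevalence 0.28 / 0.40) by truncating at 30 kg/m², so flag and value
never disagree.

Post-SBT observations are constructed so the outcome classifier reproduces
the group label: success records receive a PaCO₂ shift of +2.4 ± 4.4 mmHg
redrawn until the post value stays ≤ 45, and vitals truncated inside the
non-failure ranges; failure records receive +10.2 ± 7.2 mmHg redrawn until
the post value exceeds 45. Seven failure records (configurable) have no
post-trial blood gas and instead carry an overt tachypnoea violation,
mirroring the published missing-ABG pattern. Trial duration is 30 min for
successes and uniform 8–30 min for aborted trials.

What the generator does **not** emulate: inter-variable covariances within
group (the study publishes none, so primitives are independent within
group), longitudinal trajectories, and multi-centre heterogeneity. Because
within-group correlations are absent, cohort-level moments of *derived*
indices (e.g. the published LTC_dyn-MP mean of 7167 cmH₂O²/min) are
approximated but not matched exactly; discrimination of the derived indices
on synthetic cohorts is therefore a lower-bound-style check, not a
patient-level reproduction. A known-mechanism alternative,
`generate_logistic_cohort`, draws the index from a stated normal and the
outcome from a stated logistic model; it is the substrate for odds-ratio
recovery tests where the true effect must be exact.

## Diagnostic evaluation

The positive class is SBT failure and a higher index predicts failure for
every index except LTC_dyn, which runs the other way (failing patients are
stiffer); the report layer negates that one score so a single decision
direction applies. AUROC is the tie-adjusted Mann–Whitney pair statistic
(identical to the trapezoidal area of the ROC built on attained
thresholds), its confidence interval is DeLong, and the p-value tests
AUROC = 0.5 by the DeLong standard error. Proportion intervals are exact
Clopper–Pearson; likelihood-ratio intervals use the log method. Degenerate
tables follow fixed conventions: MCC and F₁ are 0 when a marginal is
empty; infinite PLR/DOR are returned as +inf, not errors. Thresholds are
always attained score values (no midpoint interpolation) so any reported
threshold can be audited against the data; Youden-J ties break toward the
higher threshold, i.e. higher specificity.

Cross-validation is stratified, 2-fold, repeated twice by default. Each
repeat draws a fresh seeded partition in which fold sizes differ by at most
one overall and per class. Thresholds are learned strictly on training
folds — permuting test-fold labels provably cannot change them, and a test
asserts exactly that. Metrics are aggregated as the unweighted mean over
the k×repeats test folds, and interval bounds as the mean of fold-level
bounds (a pooled-counts aggregation is available as an option). A
single-class test fold is excluded with a logged warning rather than
poisoning the mean.

## Regression layer

Between-group tests follow the study's selection rule: continuous variables
are screened per group with the Lilliefors-corrected Kolmogorov–Smirnov
normality test at α = 0.05, then compared by Student's t (both groups
normal) or Mann–Whitney U; categorical variables by chi-square, or Fisher's
exact test when any expected cell is below five. These routes are verified
against an independent R oracle to 1e-8 on frozen fixtures.

Logistic models are maximum-likelihood fits (Newton/IRLS, ≤ 50 iterations,
tolerance 1e-10) with Wald standard errors from the observed information;
statsmodels performs the optimization behind this surface. Complete
separation and non-convergence raise explicit errors. Odds ratios are
reported per caller-chosen unit (per 1000 cmH₂O²/min for the
compliance-normalized indices, per 0.01 J/min/kg for PBW-MP). Forward
selection screens candidates by univariable likelihood-ratio p < 0.2,
always admits the a-priori covariates to the pool, and greedily adds the
best variable while its likelihood-ratio p is below the entry threshold
0.05 (configurable; both thresholds are design choices where the source
leaves the rule open), with alphabetical tie-breaking for determinism.
Goodness of fit uses the Hosmer–Lemeshow decile chi-square (duplicate
quantile bins merged with adjusted df) and Nagelkerke's rescaled Cox–Snell
R². Pearson correlations carry Fisher-z intervals. No multiple-testing
correction is applied, matching the source analysis.

## Numerical and design choices

- Randomness: every stochastic routine takes an explicit integer seed and
  uses `numpy.random.default_rng`; identical seeds give byte-identical
  cohorts, partitions and report CSVs.
- Degenerate inputs: domain errors carry the patient id in panel
  computation; CSV validation aggregates all offending rows before raising.
- Report precision: machine-readable CSVs carry full double precision;
  rounding happens only in display strings.
- Test problem sizes are chosen to keep the full suite under a minute on a
  single core: law-of-large-numbers checks run at n = 10⁴ per group,
  Wald-coverage at 200 seeds × n = 2000, odds-ratio recovery at n = 5000.

## Known limitations

- The exponent form of the Power index reproduces the published magnitudes
  but the original supplementary definition was not available for verbatim
  confirmation; the exponent is therefore exposed as a parameter.
- Synthetic cohorts match group-wise marginals, not joint distributions;
  absolute values of cross-validated metrics on synthetic data sit near,
  but not exactly at, the published ones.
- Only complete-case handling of missing post-trial blood gases is
  implemented (mirroring the seven missing observations in the source
  cohort); no imputation.
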