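# Methods

This note documents the statistical procedures the package implements, the
choices made where the underlying definitions leave room, and what the
synthetic-data tests do and do not establish.

## Index construction

All eight variants are linear functionals of z-scored intake data; in every
variant a higher score means lower adherence to the Westernized dietary
pattern.

**Z-referenced family (WDI-G/GC/GS and WDI-P/PC/PS).** Each food component
is z-scored against reference statistics — external "global" means/SDs for
the G family, the analysis cohort's own statistics for the P family — and
the coefficient-weighted z-scores are averaged over the scored components.
Component aggregation follows the component's declared kind:

* *single*: z-score of the raw column;
* *mixed-unit group* (e.g., vitamins, minerals, and secondary plant
  metabolites, whose members are measured in different units): each member
  is z-scored separately and the member z-scores averaged — averaging on the
  standardized scale is the only unit-free option;
* *same-unit group* (e.g., fruits): member intakes are summed and the sum is
  z-scored against the reference mean/SD **of the summed variable**. Whether
  the reference SD of a summed group should be the SD of the sum or some
  combination of member SDs is not fixed by the verbal definition; we use
  statistics of the summed variable, which keeps the z-score exact rather
  than an approximation that ignores member covariance.

The divisor is the number of components actually scored, recorded per
variant in the output sidecar. In the reference configuration dietary
supplements have no intake data, so 29 of 30 components are scored; the
item-level and food-group variants use 57 items and 18 groups respectively.

**Centralized coefficients (GC/PC).** Raw coefficients are mapped through
their fractional rank r_i = rank_i/n (ascending; ties receive the mean rank)
to 2·r_i − 1 ∈ (−1, 1]. This is the common "fractional rank as percentile"
convention; the alternative (rank − 0.5)/n dialect — which is symmetric
around 0 and never attains 1 — is *not* used. The transform is monotone, so
rank order is preserved; with a single coefficient the centralized value is
1 by construction.

**Standardized variants (GS/PS).** The G/P score is re-standardized to the
cohort: (score − mean)/SD with the sample (n−1) SD. Output mean/SD are 0/1
to 1e−8 by construction (checked in tests); the transform is invariant to
positive affine maps of its input.

**Weight-then-standardize variants (WDI-I, WDI-FG).** Each item (WDI-I) or
each 18-partition food-group sum (WDI-FG) is multiplied by its coefficient
*first*; the within-cohort z-scores of the weighted columns are then
averaged. An algebraic consequence: z(c·x) = sign(c)·z(x), so these variants
respond only to the coefficient's sign, not its magnitude. We document this
as a mathematical property of the construction (verified numerically in the
tests) without claiming it was intended by the index's designers.

**Numerical conventions.** Sample (n−1) SDs everywhere, matching standard
statistical-package defaults. A subject missing any scored component gets a
missing score for that variant — no silent imputation; an explicit
`impute="mean"` switch performs column-mean imputation with a warning. A
component with zero reference variance is skipped with a warning and the
divisor reduced: a constant column carries no between-subject information
and its z-score is undefined. If *every* weighted column is constant
(possible only in degenerate cohorts) the weight-then-standardize score is
defined as 0. Scores are reported to 4 decimals, derived effects to 2.

**Range effects.** `effect_per_range_fraction(β, span, f)` returns
|β|·f·span rounded to 2 decimals, using the unrounded span (f·span = 0.314
for a span of 3.14 at f = 0.1, not a pre-rounded 0.31).

## Metabolic-syndrome classification

Three rule sets ship as defaults, all fully configurable (sex-specific
thresholds, comparison operators, mandatory criterion, minimum criterion
count):

* **WHO (1999)**: mandatory glucose-dysregulation arm plus ≥ 2 of obesity
  (BMI > 30 kg/m² or WHR > 0.90 male / 0.85 female), dyslipidemia
  (TG ≥ 150 mg/dL or HDL < 35/39 mg/dL male/female), and blood pressure
  ≥ 140/90 mmHg. The insulin-resistance arm is approximated by fasting
  glucose ≥ 110 mg/dL because insulin/HOMA measurements are not part of the
  phenotype table — **this is a deliberate approximation**, configurable,
  and should be replaced where insulin data exist.
* **NCEP ATP III**: any 3 of 5 — WC > 102/88 cm, TG ≥ 150 mg/dL,
  HDL < 40/50 mg/dL, BP ≥ 130/85 mmHg, FBG ≥ 100 mg/dL (the updated
  glucose criterion).
* **IDF (2006)**: mandatory central obesity (WC ≥ 94/80 cm) plus ≥ 2 of the
  remaining four ATP III-style criteria.

The minimum-criteria count applies to the *non-mandatory* criteria.
Thresholds compare with ≥ for "raised" criteria and < for "low HDL",
following the published wording. Medication/diagnosis flags are not modeled;
criteria rely on measured values only. Missing data: a criterion is
undecidable if no clause is decidably true and at least one input is
missing; the label is missing only when undecidable criteria could change
it (a subject already meeting three ATP III criteria is positive regardless
of a missing triglyceride value, and a subject failing IDF's mandatory
waist criterion is negative regardless of anything else). Derived measures:
BMI = weight/height², WHR = WC/HC, MAP = DBP + (SBP − DBP)/3.

## Validation battery

* **Group comparisons**: two-sided Welch (unequal-variance) t-tests with
  per-group mean ± SD.
* **Association models**: logistic and linear fits are delegated to
  statsmodels (this package is a harness around them, not a re-
  implementation). Wald 95% CIs on the link scale, exponentiated for odds
  ratios. Complete-case analysis per model with n reported. Adjustment
  sets: crude; age + sex; full = age, sex, physical activity (METs),
  smoking, total energy.
* **ROC/AUC**: the Wilcoxon–Mann–Whitney rank statistic
  AUC = P(score_case > score_control) + ½·P(tie), which equals the
  trapezoidal area under the empirical ROC. Because higher index scores are
  protective, the score is negated whenever the as-is AUC falls below 0.5,
  and the orientation is recorded; cutoffs are reported on the oriented
  scale.
* **Youden cutoff**: exhaustive scan of J = sensitivity + specificity − 1
  over thresholds placed midway between consecutive distinct scores
  (predict positive at score ≥ cutoff); ties in J resolve to the smallest
  cutoff. With a single distinct score the cutoff degenerates to that value
  (sens 1, spec 0, J 0).
* **k-means**: two clusters on z-standardized biomarker columns (without
  standardization the triglyceride column dominates the Euclidean metric),
  scikit-learn Lloyd's algorithm with 10 restarts and a mandatory seed.
  The cluster with the higher triglyceride center is labeled "unhealthy";
  centers are reported back on the original measurement scale. Default
  biomarker panel: WC, DBP, SBP, FBG, TG, total cholesterol, LDL-c, HDL-c
  (configurable).
* **No multiple-testing adjustment** is applied anywhere; p-values are
  reported unadjusted.

## Synthetic cohort generator

One latent healthy-diet factor W ~ N(0, latent_sd²) drives everything:

* item intake = exp(loc + λ·W/latent_sd + s·ε), ε ~ N(0,1) — log-normal,
  hence non-negative and right-skewed as dietary intake data typically are.
  Default loadings λ = 0.35 × the item's example coefficient (sign-aligned,
  so healthier items rise with W), default log-scale s = 0.5, locations set
  to log typical daily amounts. A gamma alternative with matched median is
  available behind a config flag.
* biomarker = baseline + effect·W/latent_sd + noise. Baselines and residual
  SDs follow typical adult cohort summaries (e.g., FBG 92.9 ± 26 mg/dL,
  TG 132 ± 65 mg/dL, WC 93.2 ± 10.5 cm); default effects per latent SD are
  negative for adverse markers (FBG −8, TG −30, DBP −3, WC −3.5 …) and
  positive for HDL-c (+4), planting the protective direction: higher index →
  healthier profile. SBP is generated as DBP + pulse pressure (floored at
  5 mmHg) so SBP > DBP always holds. Biomarkers are floored at 1.0 to avoid
  non-physical values; for TG this truncates roughly the lower 2% of the
  distribution and slightly attenuates the planted TG slope — recovery
  checks therefore use FBG, where truncation is negligible.
* covariates (age 48.9 ± 9.4 y, 55.8% female, METs 41.4 ± 11.2, smoking
  8.2%, energy 2922 ± 1134 kcal) are independent of W by default; a
  `confounding` knob (years of age per latent SD) couples age to W to
  exercise covariate adjustment.

The generator's truth (per-subject W, planted effects) is stored alongside
the outputs and consumed only by tests. The seed is mandatory and never
defaulted.

**What passing tests show — and don't.** The generator produces a
single-factor diet structure with log-normal margins and linear biomarker
links. Real FFQ data have multi-factor structure, measurement error,
day-to-day variation, energy-intake coupling, and heavier tails; parameter
recovery and sign-consistency on these cohorts demonstrate that the
*algorithms* are correct and well-composed, not that the index is valid in
any particular real population.

## Problem sizes

Cohort-scale checks use n = 2000 subjects (association recovery across 20
seeds, within 3 standard errors of truth), n ≈ 300–1000 for end-to-end
report tests, and ≤ 5 × 5 fixtures for exact (1e−10) brute-force oracle
comparisons — sizes at which the sampling error of each check is far
smaller than the effects being detected.

## Known limitations

* The published coefficient table, global reference statistics, and
  cohort-specific MetS cutoffs are not bundled; shipped examples are
  synthetic and non-authoritative, so absolute score values on real data
  depend entirely on the supplied config.
* WHO classification approximates insulin resistance by fasting glucose.
* The weight-then-standardize variants ignore coefficient magnitude (see
  above); users comparing variants should be aware the item/group variants
  encode strictly less of the coefficient information.
* Energy adjustment of intakes and nutrient-database linkage are out of
  scope; intakes are taken as provided.
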