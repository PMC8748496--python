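# Methods

`repurpose` implements a drug-repurposing screen in four stages: disease
gene-expression signatures, perturbation-library reversal matching,
self-controlled case-series (SCCS) cohort construction from longitudinal
EHR tables, and paired mixed-effects treatment-effect estimation. This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## Disease signatures

The input is an imputed differential-expression table: one row per gene
with an association Z-score and two-tailed p-value, the output schema of
transcriptome-wide imputation tools such as S-PrediXcan. Two selection
rules are provided:

* **top-K** (`select_topk`, default K = 50): the K most upregulated and K
  most downregulated genes, up to 2K total. Ties in Z break by ascending
  p-value and then gene symbol so output is identical across platforms.
* **FDR** (`select_fdr`, default q < 0.05): Benjamini–Hochberg q-values
  computed over all genes in the table; genes below the cutoff enter the
  signature with direction from the sign of Z.

Genes with Z = 0 carry no direction and are excluded from both rules with
a warning. Duplicate gene symbols in the input collapse to the record with
the smallest p-value ("most significant measurement wins"), and the
collapse count is logged so audits can reconcile gene counts. An optional
`restrict_to` gene list intersects the table with externally nominated
causal genes before selection, for diseases where a curated causal-gene
set exists.

## Reversal matching

A drug signature is a gene → differential-expression profile. The score
against a disease signature is the Pearson correlation over the exact
(uppercased) gene-symbol intersection; no alias resolution is attempted,
which keeps matching deterministic. p-values use the two-tailed t
transform with n − 2 degrees of freedom. Gene weights (for example |Z|)
can be supplied for a weighted-correlation sensitivity analysis; the
default is unweighted. Results with |r| = 1 report p at machine epsilon
with a degeneracy flag rather than 0, so −log10(p) displays stay finite.
With exactly 2 shared genes r is reported without p; with fewer the result
is flagged undefined.

A screen retains drugs with r < 0 and p below a per-disease alpha
(defaults 0.05 and 0.001 are both plain config values), sorted by
ascending r. Candidate lists from the two signature constructions are
merged by union, keeping the most negative r as representative and
recording which construction(s) found each drug. An ingredient map then
collapses salts/formulations to ingredients and drops unmapped and
(optionally) non-prescription entries.

## SCCS cohorts

For one candidate ingredient, each person's observation window is anchored
on the **index date**, the first outpatient exposure:

* baseline: `[index − 365 d, index]`, closed on both ends — a measurement
  on the index date is baseline (the boundary assignment is a package
  convention; days, not calendar months, are used throughout so behavior
  is locale-independent);
* treatment: `(index, min(last exposure end, index + 365 d)]`, requiring
  at least 30 days of exposure; the first 30 days are an induction period
  whose measurements are discarded so drug levels approach steady state.

Missing exposure end dates are imputed as start + 90 days (configurable
days-supply). The exclusion cascade runs in fixed order with per-step
attrition accounting: (1) age at index in [18, 90); (2) ≥1 outpatient
biomarker measurement in baseline and in the post-induction treatment
period; (3) no exposure to an approved drug for the target disease —
other than the tested drug itself — overlapping the window (this is the
confounding-by-indication guard); (4) ≥2 distinct outpatient measurement
dates within a 730-day span inside the window (an information-leakage
guard against fragmented records); (5) optionally, systemic-route
exposures only. Drugs whose final cohort is below 20 persons are flagged
untestable rather than fit.

Per-period medians use outpatient values only. The outlier screen drops a
person when either period median falls outside the Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) computed per period across the cohort, with
quartiles by linear interpolation; whether the original design removed
outliers per period or jointly is ambiguous, so this per-period,
per-person choice is documented rather than claimed as canonical. Cohorts
under 4 persons skip the screen.

The Elixhauser comorbidity index counts categories with ≥1 condition code
(ICD-prefix matching) between the observation start and the end of the
respective period, so the treatment-row index is never smaller than the
baseline-row index. The default is the unweighted category count; a
weight table (e.g., van Walraven) can be supplied. The built-in prefix map
covers ten common categories and is meant for synthetic data; real
analyses should supply a full 31-category map via `elixhauser_map.tsv`.

## Treatment-effect model

The model table has two rows per person (baseline/treatment). The fit is

    biomarkerVal ~ b0 + b1 drugExposure + b2 Age + b3 Gender
                   + b4 Ethnicity + b5 Comorbidity + (1 | person)

by REML, with Age (at the end of each period) and Comorbidity z-normalized
within the cohort, Gender coded 1 for female, Ethnicity 1 for non-white.
Inference on b1 is Wald with normal quantiles: standard, stable for
two-observation clusters, and adequate at the cohort sizes targeted;
small-sample degrees-of-freedom corrections (Kenward–Roger, Satterthwaite)
are deliberately out of scope. Reported p-values floor at 2.2 × 10⁻¹⁶.
On a balanced paired table with no covariates the GLS estimate of b1
equals the mean within-person difference regardless of variance
components, which gives an exact independent oracle: the paired t-test
(`paired_difference_oracle`). Non-converging fits fall back to that oracle
and are flagged so batch screens stay total.

Classification: *therapeutic* = negative estimate with p < 0.05;
Bonferroni significance uses 0.05 / (number of drugs tested). Demographic
reports use paired Wilcoxon signed-rank tests for continuous variables and
continuity-corrected McNemar tests per comorbidity category, with any
subgroup count under 20 suppressed for privacy-style reporting parity.

## Synthetic data

The generator's defaults define the study conditions used by the test
suite and the acceptance script:

* **DEG tables**: 5,000 genes, 300 causal with |Z| ~ N(6, 1) (random
  sign), null genes Z ~ N(0, 1); p is the two-tailed normal tail. At this
  effect size the FDR rule recovers ≥90% of causal genes, so signature
  construction is exercised in a high-power regime.
* **Libraries**: planted reversers are negated signature scores plus
  Gaussian noise scaled so the expected correlation with the signature is
  −fidelity (default 0.9); decoys and off-signature genes are independent
  standard normal, so decoy retention at alpha has expectation alpha/2
  (negative tail only).
* **EHR**: per person, an index date, uniform age 25–80, Bernoulli(0.5)
  female, Bernoulli(0.3) non-white, exposure duration uniform 90–360 days
  (10% of end dates missing, with the true course matching the 90-day
  imputation so the generator and pipeline agree), outpatient visits at
  about 6 measurements/year. Values follow
  `mean + person intercept + covariate terms + delta·(post-induction) + noise`
  with LDL-C-like defaults: mean 130 mg/dL, person-intercept sd 10,
  residual sd 5, age +3 per decade, female −3, non-white +2, +2 per
  comorbidity category. The injected effect enters only after the 30-day
  induction, matching the estimand the pipeline targets. The age term
  uses age at the end of the period a measurement falls in — the same
  covariate definition the model uses — so the estimator is evaluated
  against a correctly specified data-generating process. The
  between-person spread of ~130 ± 25 seen in outpatient LDL-C arises here
  from the intercept sd plus covariate contributions.
* **Planted violations**: under-age persons, persons missing baseline
  measurements, approved-drug co-exposure (which also shifts the
  baseline up by 10 and subtracts 30 from post-co-exposure values — the
  confounding-by-indication stressor), and non-systemic-route exposures.
  Clean persons are constructed to pass the whole cascade, so the
  cascade's removals can be checked for exact set equality against the
  truth manifest. Optional per-person non-adherence attenuates delta and
  is off by default.

What the generator does **not** emulate: realistic ICD code frequencies,
dosing and titration, visit-time dependence on disease severity,
measurement error heteroscedasticity across laboratories, or correlated
multi-drug exposure histories. Passing tests therefore demonstrate that
the pipeline's logic and inference are correct under its stated
assumptions, not that real-EHR confounding beyond the modeled mechanisms
is handled.

## Problem sizes and numerical choices

The test suite and acceptance script run the recovery and calibration
studies at 300 persons/drug with 100 replicates per injected effect
(−30, −5 mg/dL), 200 null drugs for the type-I error rate, and 25
replicate pairs for the confounding demonstration; the acceptance script
uses 30 replicates per effect and 100 null drugs. These sizes give
Monte-Carlo standard errors a few percent of the quantities checked while
keeping a full run in minutes on one CPU. All randomness flows from a
single seed per run; generators use fixed offsets from it so stages are
independently reproducible.

Known limitations: the Wald-z intervals are mildly anticonservative below
~50 persons; per-person visit counts make median precision heteroscedastic
across persons, which the homoscedastic residual model ignores (coverage
at the default conditions is nevertheless nominal, as the calibration
tests measure); and the weighted-correlation and concordance variants of
library matching are exposed as hooks without a claim of equivalence to
any particular platform's internal scoring.
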