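# repurpose

Signature-reversal drug repurposing with EHR-based clinical validation.

`repurpose` is for computational drug-repurposing researchers who want to
go from genetically imputed disease expression signatures to clinically
validated candidate drugs in one reproducible pipeline:

1. **Signatures** — build a disease gene-expression signature from an
   imputed DEG table (gene, Z, p), either the top-K most up-/downregulated
   genes (K = 50, i.e. 100 genes) or all genes at Benjamini–Hochberg
   q < 0.05.
2. **Reversal screen** — correlate the signature against every profile in
   a drug perturbation library (LINCS/DrugMatrix-style); candidates are
   drugs with Pearson r < 0 and p below a per-disease alpha, merged across
   both signature constructions and mapped to prescribable ingredients.
3. **Clinical validation** — for each candidate, build a self-controlled
   case-series cohort from longitudinal EHR tables (baseline up to 365
   days before first exposure, treatment up to 365 days after, a 30-day
   induction period, adult-age / both-period-measurement / approved-drug /
   two-visit exclusions with attrition accounting, 1.5×IQR outlier
   screen, Elixhauser comorbidity index) and estimate the biomarker
   treatment effect β₁ with a paired linear mixed model

       biomarkerVal ~ β₀ + β₁ drugExposure + β₂ Age + β₃ Gender
                      + β₄ Ethnicity + β₅ Comorbidity + (1 | person)

   where each person contributes a baseline and a treatment row and β₁ is
   the adjusted change in the median biomarker (mg/dL for LDL-C, mmHg for
   SBP). A drug is *therapeutic* when β₁ < 0 with p < 0.05; Bonferroni
   significance uses 0.05 / (drugs tested).
4. **Replication** — compare two validation summaries drug-by-drug
   (replicated effects, CI overlap) and export forest-plot data.

A synthetic-data generator produces every input — DEG tables, perturbation
libraries with planted reversers, and EHR extracts with known injected
effects and planted exclusion violations — so the whole pipeline is
testable end to end without restricted clinical data.

## Worked example

```sh
repurpose simulate --outdir demo --seed 17 --n-persons 40 --n-drugs 80
repurpose screen demo/config.yaml
repurpose validate demo/config.yaml
```

which prints

```
bundle written to demo
4 candidate(s) -> demo/results/candidates.tsv
3 drug(s) tested, 1 untestable -> demo/results/summary.tsv
```

The simulated bundle plants four candidate ingredients with known true
effects (−30, −5, 0 mg/dL, and one 19-person cohort). The screen finds the
planted reversers in the 80-drug library and maps them to those
ingredients; validation then recovers the injected effects.
`demo/results/summary.tsv` begins

```
# disease=synthetic-disease	biomarker=LDL-C
# n_tested=3	bonferroni_threshold=0.0166667
drug	n	estimate	ci_low	ci_high	p	...	therapeutic	bonferroni_significant
cand-null	38	-0.173	-1.458	1.113	0.79	...	False	False
cand-strong	40	-30.034	-31.491	-28.577	2.2e-16	...	True	True
```

`cand-strong` (true effect −30 mg/dL) is recovered at −30.0 [−31.5,
−28.6] and classified therapeutic and Bonferroni-significant; the null
drug's CI covers 0. The planted 19-person drug lands in
`demo/results/untestable.tsv` because cohorts under 20 persons are not
fit, and `demo/results/attrition_<drug>.tsv` records the per-step
exclusion counts for each cohort.

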