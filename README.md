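# methylscreen

Quantitative bisulfite-sequencing trace scoring and censored-survival
screening of DNA methylation biomarkers.

## The problem

Promoter DNA methylation is a candidate biomarker for predicting distant
metastasis in breast cancer. One assay for it is quantitative bisulfite
sequencing: after bisulfite conversion, the cytosine fluorescence at each
CpG site in a Sanger electropherogram is proportional to the fraction of
methylated molecules, and a constant tag sequence (CGTCGTCG on the reverse
primer) provides a methylation-independent normalization signal. Screening
many candidate loci for association with censored time-to-metastasis then
needs the standard survival toolkit — Kaplan–Meier curves, the log-rank
test with median-dichotomized markers, Cox proportional-hazards models,
and time-dependent ROC analysis — plus a disciplined multi-stage design so
that a marker surviving the cascade is not a multiple-testing artifact.

`methylscreen` implements that full path for analysts working with this
assay class:

* **`methylscreen.traces`** — trace scoring: matched-filter detection of
  the normalization tag, alignment of all traces to a common tag position,
  division by the integrated tag signal, per-CpG quantification as the
  maximum of the normalized trace within ±30 data points of the peak
  positions defined by a fully methylated reference, and averaging into a
  per-sample × locus methylation score. The score is invariant to global
  amplitude and positional shift, and linear in the underlying methylation
  level.
* **`methylscreen.survival`** — survival statistics from primitives:
  the product-limit estimator, the two-sample log-rank test, Cox
  regression by Newton–Raphson on the partial likelihood (Efron or
  Breslow ties) with Wald CIs and likelihood-ratio tests, and
  cumulative/dynamic time-dependent ROC curves with Kaplan–Meier plug-in
  estimators (nearest-neighbor smoothing optional). At horizon *t*, with
  *S* the overall survivor function and *S(c,t) = P(X > c, T > t)*,

      sensitivity(c,t) = [P(X > c) − S(c,t)] / [1 − S(t)]
      specificity(c,t) = 1 − S(c,t) / S(t)

  and AUC(*t*) is the trapezoidal area of the resulting ROC.
* **`methylscreen.screen`** — the three-stage cascade: a pilot
  differential-methylation filter (score dispersion ≥ θ over ~12
  samples), a training screen requiring log-rank *p* < 0.05 **and**
  AUC > 0.6 (training-median cut point, strict inequalities), and
  independent validation at the validation cohort's own median with
  Bonferroni adjustment for the number of stage-2 candidates.
* **`methylscreen.simulate`** — synthetic traces and cohorts with known
  ground truth: Beta-distributed (bimodal by default) methylation scores,
  exponential proportional-hazards event times, independent uniform
  censoring, and clinical covariates (age group, T stage, PR status,
  grade, endocrine treatment) with realistic prevalences and missingness.
* **`methylscreen.io` / CLI** — plain-text trace CSVs, manifest and
  cohort TSVs, a spreadsheet dialect with column mapping, and TSV+JSON
  report writers.

## Worked example

Simulate a study-sized cohort — 162 patients (84 training including the
12-sample pilot panel, 78 validation), 37 loci of which one carries a true
hazard ratio of 3.7 per unit methylation score — and run the cascade:

```python
import methylscreen as ms

table, truth = ms.simulate_cohort(ms.CohortSimParams(), seed=2)
report = ms.run_screen(table)
print(report.counts)

validation = table[table.set == "validation"]
fit = ms.cox_fit(validation, ["locus_01"])
roc = ms.td_roc(validation.time_months, validation.event,
                validation.locus_01, 60.0)
```

This prints (and the objects hold):

```
{'loci_in': 37, 'stage1_pass': 37, 'stage2_candidates': 2, 'validated': 1,
 'n_pilot': 12, 'n_training': 84, 'n_validation': 78}
validation Cox: HR=3.2 (95% CI 1.6-6.7), LRT p=0.0010, n=78
validation AUC(60 months)=0.69
validation log-rank p=0.0022, Bonferroni-adjusted p=0.0044 (m=2)
validated loci: ['locus_01']
```

Reading: all 37 loci show pilot dispersion, two pass the training screen,
and only the truly informative locus survives Bonferroni-corrected
validation. Its estimated hazard ratio (3.2 per unit score, CI covering
the generating 3.7) and time-dependent AUC at 60 months (0.69) recover
the programmed effect.

The same pipeline is available from the shell:

```bash
methylscreen simulate-cohort --out cohort.tsv --seed 2
methylscreen screen --cohort cohort.tsv --out-base report
methylscreen cox --cohort cohort.tsv --term locus_01 --out-base cox
```

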