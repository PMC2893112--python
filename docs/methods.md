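# Methods

## Trace model and scoring procedure

A trace is a single-channel fluorescence intensity series from capillary
Sanger sequencing of a bisulfite-converted PCR fragment, one value per
data point. The channel carries the cytosine signal, so at each CpG site
the peak intensity is proportional to the methylated fraction of the
template molecules; everywhere else the converted sequence contributes no
signal in this channel apart from the constant normalization tag
(CGTCGTCG) appended to the reverse primer, which produces a
methylation-independent peak group.

Scoring proceeds in five steps, in order:

1. **Tag detection.** The tag is located by matched filtering: the trace
   is cross-correlated with a template of `tag_peak_count` unit Gaussian
   peaks at `peak_spacing` intervals, and the best-responding position
   within ±`search_half_width` (default 100) data points of the expected
   position wins. Matched filtering was chosen because it is robust to
   noise and exactly verifiable against a brute-force scan of the same
   objective. A response at or below `signal_floor` (default 0, i.e. any
   all-zero search region) is an error, not a silent zero.
2. **Alignment.** Each trace is shifted so its tag sits at the common
   target position (the amplicon's expected tag position); vacated
   samples are zero-filled, which is safe because quantification windows
   near the edges are clipped anyway. A shift that would push the whole
   signal out of the trace is an error.
3. **Normalization.** The tag signal is integrated over a fixed-width
   window (default the full tag region: its span plus half a peak
   spacing, configurable down to a single central peak via
   `integrate_whole_tag=False`) and every data point is divided by that
   area. Because the area scales with overall signal strength, the
   normalized trace — and hence the score — is invariant to global
   amplitude factors such as template loading or detector gain. No
   baseline subtraction is performed by default; with a nonzero baseline
   the integration window would absorb it into the normalizer.
4. **CpG quantification.** The fully methylated reference trace (every
   site at level 1) is processed identically; its peaks, found above a
   floor of 5% of the trace maximum with a minimum spacing of 8 data
   points and with the tag region masked out, define the site positions.
   Each site in a sample trace is then read as the maximum of the
   normalized intensities within ±30 data points (closed window, clipped
   to the trace bounds) of the reference peak.
5. **Averaging.** The methylation score of a sample × locus is the
   arithmetic mean of its per-site values. Scores are raw normalized
   intensities — they are deliberately not rescaled or clipped to a
   percent-methylation scale, because all downstream use is through
   median cut points and per-unit hazard ratios.

Coordinates are 0-based data-point indices with closed windows
throughout. On noiseless simulated traces the pipeline is exactly
scale- and shift-invariant and exactly linear in a common per-site
methylation level; the test suite asserts all three to 1e-9.

## Survival statistics

All estimators are implemented from primitives on right-censored
time-to-event data (months to distant metastasis or last follow-up).

* **Kaplan–Meier**: the product-limit estimator, with subjects censored
  at an event time counted as still at risk at that time.
* **Log-rank**: the two-sample statistic with the hypergeometric
  variance, chi-square with 1 df.
* **Median dichotomization**: each patient group is split at the median
  of the designated cohort's scores (its own, unless an external
  cut point such as the training median is supplied); values exactly at
  the cut point go to the low group, making the split deterministic and
  order-independent. An externally supplied cut point may put every
  score on one side; a cohort split at its own median must not.
* **Cox proportional hazards**: Newton–Raphson on the log partial
  likelihood with step-halving, tolerance 1e-9 on the objective, at most
  100 iterations. Efron tie handling is the default (Breslow optional):
  the data are continuous-time in principle but real follow-up times are
  recorded coarsely, and Efron is the better approximation at no cost.
  Rows with a missing value in any requested term are dropped per
  analysis (complete-case), and the fit reports `n_used`. Wald 95% CIs
  are exp(β ± 1.96·SE); model significance is the likelihood-ratio test
  against the null model. Estimates agree with an independent
  implementation (lifelines) to ~1e-6 and with a grid search of the
  partial likelihood to 1e-4 in the test suite.
* **Time-dependent ROC**: cumulative cases / dynamic controls. With
  S(c,t) = P(X > c, T > t) the joint survivor function,
  sensitivity(c,t) = [P(X>c) − S(c,t)]/[1 − S(t)] and specificity(c,t) =
  1 − S(c,t)/S(t). The default estimator plugs in the subgroup
  Kaplan–Meier, S(c,t) ≈ P̂(X>c)·Ŝ_{X>c}(t); this is the simplest
  variant and reduces exactly to direct empirical counting when there is
  no censoring (asserted in tests). Because the plug-in is not a proper
  bivariate survivor function it can leave [0,1] under heavy censoring,
  so estimates are clipped; a nearest-neighbor variant
  (`method="nne"`, percentile span default 0.25) replaces the subgroup
  curves with kernel-weighted conditional survival curves and avoids the
  defect at the price of a smoothing parameter. AUC is the trapezoidal
  area over the ROC points plus the (0,0) and (1,1) corners.
* **Evaluation horizon**: no single horizon is canonical, so the
  screening default is t = 60 months — well inside the follow-up of both
  cohort halves — and `horizon_scan` reports AUC at 36/48/60/80/96
  months alongside any single-horizon value so the sensitivity of a
  conclusion to the horizon is visible.

## The screening cascade

Stage 1 removes loci with no apparent differential methylation across
the pilot panel. "Apparent" has no field-standard quantitative
definition; the filter used here is the score range (standard deviation
optional) reaching θ, default 0.2 on the normalized score scale,
boundary inclusive, and every report carries a note flagging θ as a
package parameter. Stage 2 dichotomizes each surviving locus at the
*training* cohort's median (the pilot samples are part of the training
cohort by design), computes the log-rank p and the continuous-score AUC
at the horizon, and passes a locus only on p < 0.05 AND AUC > 0.6, both
strict. Stage 3 re-tests the candidates in the disjoint validation
cohort at that cohort's own median and Bonferroni-adjusts the log-rank p
by the number of stage-2 candidates; the final call is adjusted
p < 0.05, chosen for symmetry with stage 2. Validated ⊆ candidates ⊆
stage-1 survivors by construction, and the report's Bonferroni
multiplier always equals the stage-2 survivor count.

The joint p-and-AUC filter makes stage 2 conservative under the null:
with 10 null loci at α = 0.05 the expected false-candidate count per run
is bounded by 10·α = 0.5 but measures well below it (the AUC condition
removes roughly two thirds of the p-only false positives).

## What the generator emulates

`CohortSimParams` defaults describe the study population this package
targets: 162 patients (84 training of which 12 pilot, 78 validation), 37
loci, one informative locus, and five binary clinical covariates at
realistic prevalences (age > 50: 0.51; T2/T3: 0.73; PR+: 0.81; grade 3:
0.56; endocrine treatment: 0.37) with missingness for T stage (2%),
grade (17%) and endocrine treatment (1.2%). Event times are exponential
under proportional hazards, h(t) = h₀·exp(Σ β_g X_g + γ'Z), with
independent uniform censoring on [0, 120] months standing in for
administrative follow-up truncation. Weibull shapes and other censoring
schemes are not modelled; neither are batch effects or informative
drop-out.

Two calibration choices deserve explanation:

* **Score marginal Beta(0.1, 0.1).** A differentially methylated
  promoter is essentially on/off across tumors, so the marker marginal
  is strongly bimodal. Quantitatively, a hazard ratio of 3.7 per unit
  score is only a *strong* marker if the two median halves of the score
  distribution are separated by close to one unit; Beta(0.1, 0.1)
  delivers that separation, and under it the simulated training and
  validation cohorts show median-split log-rank and AUC values in the
  range a strong methylation marker exhibits (training p of a few
  thousandths, AUC ≈ 0.7). Flatter marginals make the same per-unit
  hazard ratio a weak marker and are available per locus via
  `beta_shapes_per_locus`.
* **Baseline hazard 0.0011/month** (with the default covariate effects)
  reproduces an overall event fraction near 45%, matching a training
  cohort with 39/84 events. `expected_event_fraction` computes the
  analytic event probability for any configuration by quadrature over
  the Beta marginals and enumeration of the covariate patterns; the
  simulator matches it within Monte-Carlo error (asserted at n=10,000).

`marker_only_params` switches the covariate effects and missingness off
for estimator-calibration studies where the clinical covariates are pure
nuisance: coefficient recovery and Wald coverage (n=150 per cohort,
h₀ = 0.012 for ~65% events / ~35% censoring) and the cascade power and
null-calibration studies at the study's sample sizes (h₀ = 0.006 for the
~46% training event fraction). All randomness flows through
`numpy.random.default_rng` (PCG64) from explicit seeds.

What passing these simulations does *not* show: robustness to
non-proportional hazards, informative censoring, score measurement error
correlated with outcome, or between-center heterogeneity — none of which
the generator produces.

## Problem sizes used in the checks

The repeated-simulation studies use 200 cohorts of n=150 for Cox
recovery/coverage, n=2,000 for the null time-dependent AUC, 100
replicates for cascade null calibration and 40 for cascade power at the
84/78 sample sizes. At these sizes the full test suite and the
acceptance script each complete in well under a minute on a single CPU,
while leaving Monte-Carlo margins (±0.03 on a null AUC, a few points on
a power estimate) that the assertions respect.

## Known limitations

* The trace model is single-channel; 4-channel chromatogram files must
  be reduced to the analysis channel upstream (base calling, mobility
  correction and quality scoring are out of scope).
* The stage-1 dispersion threshold θ has no data-driven default; reports
  flag it, and an analyst should sensitivity-check it on pilot data.
* The KM-plug-in ROC estimator requires clipping; prefer the NNE variant
  when censoring before the horizon is heavy.
* Bonferroni is the only built-in multiplicity correction; with many
  correlated candidate loci it is conservative.
* Wald CIs can be effectively unbounded on very small fits (a few
  events); the fit reports them as computed rather than truncating.
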