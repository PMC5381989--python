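# Methods

This note documents the models, conventions and design choices behind
`expotrans`, in the order the pipeline runs them, followed by the synthetic
data generator, the numerical conventions, and known limitations.

## Study design being emulated

Two independent cohorts of 50-65-year-old adults from the same region:

* a **discovery cohort** (48 men, 50 women; never-smokers; no cell counts)
  profiled on one-colour expression arrays;
* a **validation cohort** (75 men, 94 women; includes smokers; leukocyte
  counts and neutrophil percentages available) measured by qPCR on the
  candidate panels only.

Each participant carries a long-term (2-year annual mean) residential PM10
and PM2.5 exposure in ug/m3. Exposure modelling itself is out of scope: the
generator draws exposures directly from a calibrated joint distribution.

## Microarray preprocessing

Chain (fixed order, logged row counts):
background correction and flagging -> flagged-row filter -> quantile
normalization -> replicate-probe merging (median) -> KNN imputation ->
flat-pattern filter -> one probe per gene by IQR.

Conventions, each fixed and unit-tested:

* a cell is missing when flagged or when foreground <= background (log2 of
  a non-positive net intensity is undefined);
* rows are removed when *strictly more* than 30% of cells are missing;
* quantile normalization runs **before** imputation (it must tolerate
  missing entries): each column is rank-interpolated over its observed
  values against the pooled reference distribution (the mean of the
  columns' empirical quantile functions on a common grid). With complete
  data this is exactly the classic sort / row-mean / unsort algorithm; tied
  values receive the mean of the reference values at their tied ranks;
* replicate spots of a probe are merged by the per-sample median (mean of
  the central pair for even counts; missing values are skipped);
* KNN imputation (K = 15) is gene-wise: distance between rows is Euclidean
  over the samples observed in both, divided by sqrt(shared count);
  neighbours must have the target sample observed; the imputed value is the
  unweighted mean of the K nearest. Fewer than K eligible neighbours: use
  all, with a warning;
* the flat filter removes rows whose mean-centred RMS is strictly below
  0.25 log2 units (a row exactly at 0.25 is retained);
* per gene, the probe with the largest IQR (Q3 - Q1, linear-interpolation
  quantiles) is kept; ties go to the lexicographically smallest probe id.

## Per-gene exposure models

OLS of log2 expression on exposure plus covariates, stratified by sex.
Covariate encodings: age and BMI continuous; SES (low/medium/high), season
(cold/warm), daytime (4 bins), smoking (never/former/current) as dummies
with the first category as reference; levels unobserved in a stratum
produce no column (this keeps the design full rank; contrasts cannot affect
the exposure coefficient). Rank deficiency is an error naming the collinear
columns.

The visual residual-outlier screening used in this kind of analysis is
formalised reproducibly: observations with |externally studentized
residual| > 4 are dropped once and the model refit; the count is reported
per gene. A zero-variance response returns slope 0, p 1, flagged as
degenerate, so NaNs never propagate.

Fold change per increment: `FC5 = 2^(5*beta)` with a t-based CI. The same
5 ug/m3 increment is used for PM2.5 models (the convention is stated here
because it is a choice, not a necessity). BH q-values are computed within
each sex-by-exposure family separately, since significant-gene counts are
reported per sex. Ranks are ascending p with lexicographic tie-break.

The pooled sex-interaction scan adds a sex main effect and a
sex-by-exposure product term and reports the product-term p per gene.

## Gene-set enrichment

Per set, the measured members' log2 fold changes are tested against
symmetry about zero with a Wilcoxon signed-rank test: zeros dropped,
midranks for ties, **two-sided** (the null is "around zero", with no
directional claim). The p-value is exact — full enumeration of the 2^n sign
assignments via integer convolution — for n <= 25, and a tie-corrected,
continuity-corrected normal approximation above. Sets enter only when their
number of *measured* members (not nominal size) lies in [5, 100]; BH across
the retained family. No over-representation mode and no pathway-database
client are provided; gene sets are a GMT input.

## Candidate selection (meet-in-the-middle)

Per sex: the 50 genes with the smallest uncorrected p-values are
intersected with a disease-annotation table (controlled vocabulary:
allergy, COPD, asthma, lung cancer, CVD, CeVD, Alzheimer, cognition), and
the 8 lowest-p annotated genes form the panel. The rule is deliberately
"top-k AND annotated", not "p < 0.05 AND annotated": a gene can enter a
panel with p slightly above 0.05 if it sits in the top 50 — this matches how
such funnels behave in practice. The literature search itself is
externalized: the annotation table is an input file; a 16-gene example
table with published disease links ships with the package.

Concordance verdicts for validated genes: **confirmed** (validation
p < 0.05 and same direction as discovery), **opposite_direction**
(significant, flipped), else **not_significant**; a borderline flag marks
0.05 <= p < 0.10 and never upgrades a verdict — "borderline significant" and
"confirmed" are kept as separate claims.

## qPCR quantification

Triplicate rule: replicates deviating >= 0.5 cycles from the triplicate
median are excluded; at least two concordant replicates are required, else
the well is missing. (The 0.5-cycle inclusion tolerance is standard; the
median is the reference point because it is robust and deterministic for
three replicates.)

Relative quantity: `RQ = E^(Cq_cal - Cq)` with per-assay efficiency E
(accepted as percent 90-110 in files, converted to E = 1 + pct/100) and the
**per-assay mean Cq across samples** as calibrator. Any other calibrator
(sample minimum, inter-run calibrator) only shifts log2 NRQ by a per-assay
constant and cannot change regression slopes; the mean is used because it
is the most common software default. Normalization factor: geometric mean
of the three reference-gene RQs (HPRT, IPO8, YWHAZ); two usable references
are accepted with a warning, fewer drop the sample. `NRQ = RQ / NF`;
log2 NRQ feeds the validation regression.

Properties tested: a global per-sample Cq shift cancels exactly when assays
share E; with zero noise the chain returns the generator's embedded log2
expression up to per-assay constants, so validation regression recovers
embedded slopes.

## Exposure classification

Exposure is dichotomized at the 75th percentile (linear-interpolation
percentile; high = strictly above). The panel score is a logistic
regression on per-gene standardized log2 expression, fit by maximum
likelihood; a fixed small ridge (C = 1000) is engaged automatically only
when perfect separation is detected, keeping the fit deterministic and
finite. AUC is the Mann-Whitney statistic (ties = 1/2); inference is DeLong
variance with a Wald 95% CI truncated to [0, 1] and a two-sided test of
AUC = 0.5; with fewer than 5 samples in a class an exact permutation p
(<= 10,000 resamples) replaces the asymptotics.

Both the **in-sample** AUC (the usual reporting convention for fitted
panels, optimistically biased) and a **5-fold stratified cross-validated**
AUC are always reported, clearly labelled. Whether expression or exposure
is standardized first is irrelevant to the AUC (monotone invariance).

## The synthetic-data generator

The generator defines the study conditions; its defaults are calibrated to
the cohort descriptives above and are not tuned per experiment.

* **Exposures**: bivariate log-normal parameterized by arithmetic mean/SD
  and scale correlation (defaults: discovery PM10 25.9 +/- 2.8, PM2.5
  17.8 +/- 1.7; validation 23.7 +/- 2.3 and 15.7 +/- 1.2; correlation
  0.85). The SD 2.8 puts the discovery 5th-95th percentile range near
  21.5-30.4 ug/m3. Log-normality gives positivity and the right skew of
  ambient concentrations; the latent correlation is solved exactly from
  the requested scale correlation.
* **Covariates**: age ~ Normal(58, 4.2) truncated to [50, 65]; BMI ~
  Normal(26.2, 3.9) clipped; SES/smoking/season/daytime multinomial with
  cohort-kind-specific frequencies (discovery: smoke-free, mostly cold
  season, morning sampling; validation: 57% ever-smokers, afternoon
  sampling); leukocytes and neutrophils only in the validation cohort.
* **Confounding** is real, not cosmetic: the cold season shifts the latent
  exposure scale (+0.3 latent SD, centred so means stay calibrated) *and*
  expression (default covariate effects: season +0.10 log2, age 0.004/yr,
  BMI 0.008 per kg/m2), so covariate adjustment is actually exercised. The
  shift is proportional to the latent SD, so a zero-SD (degenerate)
  exposure stays an exact point mass.
* **Expression**: `log2 x = mu_g + (log2FC5/5)*PM*[sex match] + covariate
  terms + eps`, eps ~ Normal(0, residual_sd). Baselines are Uniform(6, 12)
  log2 units. Residual SD defaults to 0.4 log2 units and the Cq replicate
  SD to 0.1 cycles — typical magnitudes for whole-blood arrays and qPCR
  triplicates, stated here as defaults because such dispersions are rarely
  printed in cohort reports.
* **Probes**: genes cycle deterministically through 1-2 probes x 1-2
  replicate spots; spot values add a per-probe offset and per-cell noise
  (SD 0.05). `foreground = background + 2^value` with background ~
  Uniform(20, 80) makes background subtraction exactly invertible; flags
  are Bernoulli (default 1%) and flagged cells are treated as missing, not
  zeroed.
* **Cq tables**: `Cq = c_assay - log_E(Q)` with log2 Q following the same
  linear model (reference genes carry no exposure effect, enforced);
  triplicates add Normal(0, 0.1) cycles, and with 2% probability one
  replicate is displaced by 0.8-1.6 cycles to exercise the concordance
  filter.

What passing tests on these data do **not** show: real arrays have
correlated probe noise, intensity-dependent variance, batch structure and
43k probes; real blood expression has correlated genes and cell-composition
variation; real exposure error is spatially structured. Calibration results
here validate the estimators under the stated model, not robustness to
those features.

### Exact recovery and quantile normalization

A noiseless-data identity test ("embedded slopes come back exactly") cannot
include quantile normalization: QN forces every column onto the common
reference distribution, so in data whose only between-sample variation is a
handful of exposure effects, an affected gene whose rank does not change
becomes exactly constant. The exact-recovery test therefore runs the chain
with QN switched off (a documented diagnostic flag), while the full default
chain is validated statistically at realistic noise, where dense baselines
make QN approximately rank-preserving and signal passes through.

## Problem sizes and determinism

The demo configuration uses 200 genes (16 with embedded effects taken from
the packaged example panel table — discovery fold changes in the discovery
cohort, validation fold changes in the validation cohort) and the cohort
sizes above; Monte-Carlo studies use 2,000 null genes (type-I error), 500
simulations (CI coverage), 5,000 replicates (signed-rank null), 1,000
replicates (null AUC), 300 simulations (FC5 recovery) and 200 repeats
(panel-AUC band). These sizes give Monte-Carlo standard errors well inside
the tested bands while keeping a full run to tens of seconds.

All randomness flows from explicit seeds through `numpy` Generators (child
streams via `SeedSequence.spawn`); reruns with the same config and seed
reproduce every data output byte for byte. The run reports
(`report.json`/`report.txt`) additionally contain wall-clock stage timings
and are the one deliberate exception to byte identity.

## Known limitations

* No empirical-Bayes variance moderation or mixed models; with ~50 samples
  per stratum the per-gene OLS t-test is exact under the model but less
  powerful than shrinkage approaches on real arrays.
* No cell-composition correction in the discovery design (cell counts are
  by construction unavailable there).
* The enrichment test treats genes as independent; correlated member genes
  inflate its significance on real data.
* In-sample panel AUCs are optimistic; the cross-validated column is the
  honest generalisation estimate, and no external-cohort transfer of a
  fitted panel is implemented.
* The disease-annotation table is an input; the package does not query
  literature databases or score annotation evidence.
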