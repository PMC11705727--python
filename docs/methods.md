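# Methods

`comos` implements a cell-free DNA (cfDNA) multi-omics classification
pipeline for liquid-biopsy cancer detection: seven per-sample feature
layers extracted from aligned cfDNA fragments and per-CpG methylation
calls, a per-omics classifier bank with specificity-targeted decision
thresholds, and a probability-stacking integrator. This note documents the
models, the numerical choices, and what the built-in simulator does and
does not emulate.

## Feature layers

All genomic coordinates are 0-based half-open (BED convention).
Methylation input files use 1-based positions (bismark-coverage dialect)
and are converted once, at the reader boundary.

**DMR methylation (`DMR`).** Differentially methylated regions are called
on the *training split only*. The caller is deliberately transparent
rather than a clone of segmentation tools: (1) per CpG site covered in at
least one sample of each group, the group-mean methylation difference is
computed; (2) candidate regions are maximal runs of sign-consistent sites
with at least `min_cpg = 4` CpGs and inter-site gaps of at most 300 bp
(the gap default is our choice; it is not dictated by any reference); (3)
each candidate is tested by a two-sided Mann-Whitney U on per-sample
pooled-count region levels; (4) Benjamini-Hochberg q-values are computed
over all candidates; (5) survivors need `q <= 0.05` and an absolute
group-mean difference of at least 20 percentage points (15 for the
treatment-response task). Levels are percentages (0-100), so the 20/15
thresholds apply literally. Selecting sign-consistent runs before testing
biases the test optimistically, which is why the practical gatekeeper on
null data is the 20-point effect-size filter; the null false-call rate is
checked empirically in the test suite. Per-sample DMR levels are
pooled-count ratios; samples missing more than 20% of DMR levels are
excluded outright (train and validation alike), and remaining missing
entries are imputed with the per-DMR mean. The imputation basis is
configurable: `all` retained samples (the classical convention) or
retained *training* samples only. The end-to-end pipeline defaults to
`train` so that no validation value can influence any training artifact;
this is the one place where the classical convention and a strict leakage
guard disagree, and we chose the guard.

**Fragment size ratio (`FSR`).** Fragments of length 100-220 bp
(inclusive) are assigned to 5-Mb genome bins when at least 50% of the
fragment overlaps the bin; the per-bin feature is the ratio of short
(100-150 bp) to long (151-220 bp) fragment counts. Tiling retains
trailing partial bins — the 22 hg19 autosomes yield exactly 589 bins at
5 Mb. A bin with zero long fragments is *missing*, never zero. Bins
missing in more than 20% of training samples are dropped from the feature
set (the threshold is configurable; real-cohort retained-bin sets also
depend on blacklist and mappability inputs the user must supply, so the
missingness rule is a pragmatic stand-in), and remaining missing values are imputed
with the training-set bin mean. Overlap ties at exactly the threshold
fraction qualify (`>=`); when two bins qualify, the larger overlap wins,
then the later bin — deterministic and consistent with `>=`-style
interval tools.

**Copy number (`CNA`).** Fragments are counted into 1-Mb bins by
midpoint. Per sample: bins with mappability < 0.5 or with zero counts in
more than 10% of the training panel are flagged (not dropped); counts are
divided by a lowess fit (span 0.3) of count vs GC, then vs mappability;
normalized by the sample median; winsorized at median ± 4 MAD of the
±2 neighbouring bins; and log2-transformed. This is a self-contained
behavioural equivalent of the standard fixed-bin read-depth pipelines
(filter → estimate/correct → normalize → smooth) with the same bin size.
Group-level gain/loss calling uses a per-bin two-sided Wilcoxon rank-sum
and the raw rule: Gain iff p < 0.05 and log2(case mean / control mean) >
0, Loss iff p < 0.05 and the ratio is negative — intentionally without
multiple-testing correction, the conventional raw-p rule for descriptive
group-level gain/loss maps. Model features are per-bin values; no within-sample
segmentation is performed.

**Breakpoint scores (`BSN`, `BSC`, `BSD`, `BSE`).** For each annotation
class — nucleosome centers, CpG islands, DNase clusters, enhancers — the
distribution of fragment 5'-end positions over offsets within ±200, ±300,
±150 and ±500 bp of the region centers, respectively. Only the fragment
*start* is a breakpoint (counting ends would double-count); counts are
pooled over all regions of a class before normalizing (robust to sparse
regions), so each profile is a probability distribution over offsets and
is comparable across sequencing depths. Annotations are treated as
unstranded. For modelling, per-offset scores are averaged in consecutive
windows (~20 features per class by default; window = (2w+1)/20 bp, the
trailing remainder dropped). Whether models should see raw per-offset
scores or window summaries is genuinely open; smoothing is exposed as
configuration and the default keeps the classifier bank comparable across
classes at desk scale.

## Classifier bank and stacking

Per omics table: z-standardization with training-split moments
(zero-variance features pass through centered, flagged); recursive
feature elimination with cross-validation (RFECV, stratified 10-fold, ROC
AUC, logistic-L2 eliminator — the eliminator is configurable because no
single choice is canonical); exhaustive grid search over three families —
logistic regression (C ∈ {0.001…100}, penalty l1/l2, max_iter
100/500/1000), random forest (100-300 trees, depth {None,10,20,30},
min-split {2,5,10}, min-leaf {1,2,4}, max-features {sqrt, log2}), and
AdaBoost (50-200 estimators, learning rate {0.01,0.1,1.0}) — scored by
stratified 10-fold mean ROC AUC with seed 42 throughout. The family with
the largest mean CV AUC wins; ties break in the fixed order logistic,
random forest, AdaBoost. Folds shrink to the smallest class count when a
class has fewer than 10 members (logged) so small cohorts run rather than
error.

A caveat stated plainly: the recorded per-omics CV AUC is computed on the
same training split that feature elimination and tuning already adapted
to, so it is optimistically biased — on signal-free data it can sit far
above 0.5. It is a model-selection statistic, not a performance estimate;
unbiased performance numbers in this package always come from the
validation split. Nested cross-validation would remove the bias but is
out of scope by design.

**Thresholds.** The decision threshold starts at 0.5 and steps up by 0.01
until training-set specificity reaches the target (0.99 by default); if
no grid point below 1 reaches it, the largest threshold attaining the
maximum specificity is used (logged). A probability exactly at the
threshold is a positive call (`>=`).

**Stacking.** The integrator is a random forest (seed 42) on the seven
per-omics positive-class probability columns in the fixed order DMR, FSR,
CNA, BSN, BSC, BSD, BSE, computed on the training split (resubstitution
probabilities by design — a known source of optimism the validation
split is immune to). 100 trees for early diagnosis; 5 for the
smaller treatment-response task to limit over-fitting. Its threshold is
calibrated the same way. Positive class: `case` (early diagnosis) and
`PDSD` (progressive/stable disease) for treatment response.

## Evaluation statistics

AUC is the rank-based (Mann-Whitney) statistic with half-credit ties.
Paired AUCs are compared with the DeLong test via placement values
(O(n log n)); a degenerate variance of the difference yields p = 1 with a
flag. Confidence intervals are 95% percentile bootstrap with 1000
resamples, stratified by class so every resample contains both classes
(an unstratified mode exists); resamples on which a metric is undefined
are redrawn and counted. Binomial proportions (per-stratum sensitivity
for early = stages I+II and late = III+IV) get Wilson score intervals.
Feature heatmaps use Z = (X − μ_control)/σ_control applied to cases and
controls alike.

## The simulator

`comos.simulate` generates cohorts with the statistical structure the
extractors target, with every group effect dialled by configuration and
all randomness driven by one seed:

* fragment lengths: two-component normal mixture, short mode 145 ± 8 bp
  with weight `w_short` (0.2 in controls — a plausible cfDNA short
  fraction; no reference value exists to match) and mono-nucleosomal mode
  167 ± 10 bp, truncated to [80, 250]; cases add `delta_w_short`;
* fragment starts: a fraction `f_window` = 0.3 anchors to a random
  annotation center — offset triangular over the class window with
  probability `p_struct` = 0.6 (with a depleted ±40 bp core around
  nucleosome centers), else uniform within the window; the rest are
  background, uniform per 1-Mb bin weighted by a smooth GC-bias curve
  and, in cases, by planted copy-number multipliers. Cases perturb
  `p_struct` by `delta_p_struct`, changing the peakedness of the
  normalized profile;
* methylation: ~3000 CpG sites at 80-220 bp spacing, baseline rates
  Beta(6, 2), coverage Poisson(30), per-sample rate jitter (SD 0.03) and
  site missingness (5%; one preset sample is pushed to 35% to exercise
  the >20% exclusion path); planted DMRs shift case rates by
  `delta_meth` percentage points over runs of 10 CpGs;
* genome: two 50-Mb chromosomes (100 Mb total) — large enough for 20
  5-Mb FSR bins and 100 1-Mb CNA bins while keeping a full pipeline run
  to roughly half a minute on one CPU.

Presets: `tiny` (6+2 samples per group, seconds, for unit tests), `null`
(all effects zero; 20 train + 10 validation per group), `signal`
(delta_w_short 0.1, eight −25-pp DMRs, two 1.5× CNA segments of 10 bins,
delta_p_struct 0.05; same cohort sizes). Ground truth is written as
`truth.json` next to the data and is never read by the pipeline (tested).

What the simulator does *not* emulate: read-level sequence artifacts,
bisulfite/enzymatic conversion errors, fragment end motifs, correlated
biological covariates (age, inflammation), realistic chromosome-scale
copy-number architecture, or inter-feature correlation structure of real
plasma. Passing tests therefore demonstrate that the implementation
recovers the effects it models under controlled conditions — not that the
classifier performance transfers to clinical cohorts.

## Problem sizes and determinism

Desk-scale runs (presets, the acceptance script) use a reduced
hyperparameter grid (`fast_grids`: logistic C ∈ {0.01, 1, 100} with l2,
random forest 100 trees × depth {None, 10}, AdaBoost 50 estimators ×
learning rate {0.1, 1.0}); the full grids listed above are the library
default and are exercised on a small separable case in the test suite.
These sizes are the package's own choice of a configuration that keeps a
30-samples-per-group, seven-omics study tractable on a single CPU.

Everything is deterministic given seeds: the simulator from its one seed,
the modelling stack from seed 42 (stratified folds, forests, boosting),
the bootstrap from an explicit seed. Re-running a pipeline with an
identical configuration reproduces byte-identical feature tables, models
and metrics; the run manifest records config hash and artifact checksums.

## Known limitations

* The DMR caller is a behavioural stand-in with matched thresholds, not a
  reimplementation of any external segmentation statistic; candidate
  selection and testing share data (see above).
* CV AUC after in-split feature selection is optimistic (see above).
* Retained-bin counts (FSR bins, CNA bins) are configuration-dependent;
  cohort-specific counts from real data depend on blacklist/mappability
  inputs outside this package and are not targeted.
* Ingesting externally produced pre-extracted feature tables through the
  modelling module is supported in principle (`ComosModel` accepts any
  sample × feature tables) but no such data ships with the package, so
  that path is a smoke test for users who have the tables, not part of
  the tested contract.
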