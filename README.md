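# comos

Multi-omics feature extraction and stacked classification for cell-free
DNA (cfDNA) liquid biopsies.

Plasma cfDNA carries several independent layers of tumour signal: tumour
DNA is hypomethylated at specific regions, more fragmented (shorter
fragments), copy-number altered, and differently positioned relative to
chromatin landmarks. `comos` turns aligned cfDNA fragments and per-CpG
methylation calls into seven per-sample feature layers, trains one
classifier per layer, and integrates them into a single stacked model —
the workflow used by multi-omics early-detection and treatment-response
studies. It is aimed at computational biologists who want a transparent,
fully tested, end-to-end reference implementation of this design that
runs on a laptop against simulated or real cohorts.

## The model

For sample *s* with fragments *F(s)* and methylation calls *M(s)*:

* **DMR** — differentially methylated regions, called on the training
  split only: maximal runs of ≥ 4 CpGs (gap ≤ 300 bp) with
  sign-consistent group differences, Mann-Whitney U per region,
  Benjamini-Hochberg q ≤ 0.05 and |Δ methylation| ≥ 20 percentage points
  (15 for treatment response). Feature: per-sample region methylation
  level (%), with > 20%-missing samples excluded and the rest
  mean-imputed.
* **FSR** — per 5-Mb genome bin, the fragment size ratio
  `#short (100-150 bp) / #long (151-220 bp)`; fragments are assigned to
  bins by ≥ 50% overlap. The 22 hg19 autosomes tile into exactly 589
  5-Mb bins.
* **CNA** — per 1-Mb bin, the log2 normalized fragment count after
  lowess GC/mappability correction, median normalization and outlier
  winsorization. Group-level calls: Gain/Loss iff rank-sum p < .05 and
  log2(T/NC) ≷ 0.
* **BSN / BSC / BSD / BSE** — breakpoint-score profiles: the
  distribution of fragment start sites over offsets within ±200 / ±300 /
  ±150 / ±500 bp of nucleosome / CpG-island / DNase-cluster / enhancer
  centers.

Each layer is z-standardized (train moments), reduced by RFECV
(10-fold, ROC AUC), tuned by grid search over logistic regression,
random forest and AdaBoost (seed 42), and the family with the best mean
CV AUC wins. Each model's decision threshold is stepped up from 0.5 in
0.01 increments until training specificity reaches 99%. The stack is a
random forest over the seven positive-class probability columns (100
trees for early diagnosis, 5 for treatment response) with its own
calibrated threshold. Evaluation: rank-based AUC, DeLong tests,
1000-resample percentile bootstrap CIs, Wilson intervals for
stage-stratified sensitivity, and Z-scores vs the control group.

A built-in simulator (`comos.simulate`) generates complete cohorts —
fragment BEDs, CpG call TSVs, annotation BEDs, sample sheet, hidden
ground truth — with configurable group effects, so the whole pipeline is
testable without any data download. See `docs/methods.md` for modelling
details, defaults and limitations.

## Worked example

```python
from comos.simulate import make_fixture
from comos.pipeline import DataBundle, PipelineConfig, extract_features
from comos.modeling import ComosModel

cohort = make_fixture("signal", seed=1)        # 30 + 30 samples
data = DataBundle.from_cohort(cohort)
config = PipelineConfig(out_dir="run", preset="signal")
tables = extract_features(data, config)            # 7 omics tables
model = ComosModel(tables, data.samples, task="early_dx",
                   config=config.model_config())
results = model.fit()
print(results.summary().round(3).to_string())
```

```
                             family  n_features  cv_auc  threshold  validation_auc  validation_sensitivity  validation_specificity
model
DMR             logistic_regression           1   1.000       0.50            1.00                     1.0                     1.0
FSR             logistic_regression           1   1.000       0.50            1.00                     1.0                     1.0
CNA             logistic_regression           1   1.000       0.50            1.00                     0.9                     1.0
BSN             logistic_regression           1   0.850       0.53            0.45                     0.0                     0.9
BSC             logistic_regression          12   0.875       0.50            0.62                     0.4                     0.6
BSD             logistic_regression          12   0.925       0.75            0.84                     0.6                     0.8
BSE             logistic_regression          17   0.825       0.50            0.67                     0.5                     0.6
stacked  random_forest (integrator)           7     NaN       0.50            1.00                     1.0                     1.0
```

Reading the table: the simulated cohort plants strong methylation,
fragment-size and copy-number effects and a weaker breakpoint effect, so
DMR/FSR/CNA models separate the validation split perfectly while the
breakpoint layers are noisy; the stacked integrator reaches validation
AUC 1.00 with sensitivity 1.0 at specificity 1.0 at its calibrated
threshold 0.50. `cv_auc` is the (optimistic) training-split
model-selection score — trust the validation columns.

The same run from the shell, with artifacts, manifest and metrics JSON:

```sh
comos run --preset signal --seed 1 --out run/
comos simulate --preset tiny --seed 0 --out data/   # just the dataset
```

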