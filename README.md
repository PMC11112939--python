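# nics

Noninvasive chromosome screening (NICS) analysis toolkit: from simulated
spent-culture-medium shallow-sequencing read counts, through copy-number
calling and mosaicism-aware feature extraction, to euploidy-probability
grading (A/B/C) and cohort outcome statistics.

## What it does

- **`nics.synthetic_data`** — simulates embryo karyotypes (whole-chromosome,
  arm-level, and segmental ≥ 10 Mb single-copy events with mosaic fractions),
  negative-binomial per-bin read counts (~2 M reads/sample) with GC bias and
  maternal-XX contamination, patient cohorts with logistic-model outcomes,
  and exact patient-level reconstructions of published aggregate cohort
  tables.
- **`nics.cnv_calling`** — GC- and reference-panel normalization of 1 Mb bin
  counts, circular binary segmentation (permutation-tested, seeded), per-
  segment mosaic-fraction estimates (`min(|cn − 2|, 1)` under the single-copy
  model), per-chromosome resolution classing and sex calling.
- **`nics.feature_extraction`** — the 11-feature vector: raw + 50 %-threshold-
  redefined ordinal calls at segmental/arm/chromosome resolution, euploid-
  resolution count, abnormal-chromosome count, highest mosaic fraction and
  its largest fragment, sex-chromosome abnormality flag.
- **`nics.grading`** — random-forest euploidy-probability classifier trained
  on labeled synthetic embryos; grades A (p ≥ 0.94), B, C (p ≤ 0.70); transfer
  ranking (A before B, C excluded, morphology tie-break) and cohort
  utilization summaries.
- **`nics.clinical_outcomes`** — rates (half-up, 1 decimal), 2×2 chi-square
  (Pearson / Yates / Fisher), hand-rolled IRLS logistic regression with Wald
  CIs and separation flagging, stratified group comparisons.
- **`nics.pipeline` / `nics.cli`** — reproducible end-to-end runs with YAML
  config, content-hash manifests, and format validators.

## CLI

```bash
nics simulate embryos --n 20 --seed 1 --depth 2000000 --out runs/embryos
nics simulate cohort --n-nics 90 --n-control 161 --true-or 2.8 --seed 1 --out cohort.csv
nics reconstruct --table age --out table3_patients.csv
nics segment --counts runs/embryos/embryo_0000.tsv --seed 0 --out-seg s.seg --out-calls c.json
nics features --callsets c.json --out features.csv
nics train --n-train 2000 --seed 0 --out-model model.joblib
nics grade --model model.joblib --features features.csv --out grades.csv
nics outcomes --patients table3_patients.csv --stratify age
nics run --seed 7 --n-embryos 50 --out runs/full
nics validate --path cohort.csv --schema patients_csv
```

Exit codes: 0 ok, 1 validation error, 2 runtime failure.

## Notes and limitations

- The original study's individual-level covariates and the trained model
  weights are not public: covariate-adjusted odds ratios on reconstructed
  aggregate tables are flagged unavailable rather than fabricated, and the
  classifier is retrained on synthetic labeled embryos with its quality
  asserted as recovery/ordering properties, not as a weight-level
  reproduction.
- Simulation starts at binned counts; no read-level (FASTQ/BAM) processing.
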