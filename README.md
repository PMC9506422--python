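# sclc-subtyper

Reusable, tested pipeline for multi-omic subtype characterization of
small-cell lung cancer (SCLC) cell-line proteomes, exercised end-to-end on
synthetic data with planted ground truth.

Stages:

- **synthetic_data** — simulate label-free intensity matrices with planted
  subtype-specific proteins, per-protein batch effects, culture-type effects,
  NE/EMT marker structure, left-censored (logistic, intensity-dependent)
  missingness, and GMT gene-set collections; all planted truth is returned
  for recovery testing.
- **preprocess** — log2 transform + median normalization, per-vial technical
  replicate median, batch-effect regression (univariate, per protein),
  replicate averaging, ≥80 % valid-value filter, down-shifted normal
  imputation (width 0.3, downshift 1.8), and on/off protein detection
  (≥85 % / ≤15 % presence rule).
- **scores** — NE and EMT signature scores (mean Z of positive markers minus
  mean Z of negative markers) and their Pearson association.
- **differential** — per-protein one-way ANOVA with BH correction and Tukey
  HSD post hoc tests; subtype-specific selection (FDR < 0.05 and all three
  pairwise Tukey p < 0.05) with direction; FC × −log10(p) rank metric.
- **enrichment** — hypergeometric ORA, pre-ranked GSEA (weighted running sum,
  gene-label permutation null, NES), the subtype-characteristic filter
  (p < 0.01 in all three comparisons, unequivocal NES sign), cross-omics
  concordance (p < 0.1 + matching sign in the other dataset), and ssGSEA
  (rank normalization, weight 0.75, area under the running score, min.
  overlap 5) with per-set min–max scaling.
- **unsupervised** — SD > 1.25 high-variance filter, consensus clustering
  (bootstrap resampling at 0.8 item/feature probability, PAM on 1 − Pearson,
  complete-linkage consensus partition), silhouette-based K selection, PCA
  coordinates, and PVCA-style variance attribution.
- **splsda** — sparse PLS-DA with per-component keepX selection, centroid
  distance classification, balanced error rate, repeated stratified 3-fold CV
  tuning, and feature-selection stability.
- **annotation** — database-overlap annotation (secreted = ≥2 of 3 DBs,
  surface = both DBs, plasma/druggable = listed) and protein abundance vs
  ln(IC50) drug-sensitivity correlation.
- **pipeline / cli** — YAML-configured orchestration with one master seed,
  per-stage derived seeds, and a SHA-256 manifest of every output; the 26-row
  cell-line characteristics table ships as a packaged fixture.

## CLI

```bash
# full synthetic run (simulate -> preprocess -> scores -> DE -> enrichment
# -> clustering -> sPLS-DA), deterministic for a given seed
sclc-subtyper run --seed 1 --out run/

# individual stages
sclc-subtyper simulate --n-proteins 800 --seed 1 --out sim/
sclc-subtyper preprocess --raw sim/raw_intensities.tsv --ann sim/annotation.tsv \
    --min-frac 0.8 --width 0.3 --downshift 1.8 --seed 1 --out pp/
sclc-subtyper de --matrix pp/processed_log2.tsv --ann pp/cell_line_annotation.tsv
sclc-subtyper enrich prerank --gmt sets.gmt --ranking ranked.tsv
sclc-subtyper cluster --matrix pp/processed_log2.tsv --sd-thr 1.25 --reps 1000
sclc-subtyper splsda tune --matrix pp/processed_log2.tsv --ann pp/cell_line_annotation.tsv
sclc-subtyper table1
```

All intensity matrices are TSV (rows = proteins, columns = samples, empty
cell = missing); gene sets are GMT; configs are YAML (`run --config`).

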