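# phosphodrug

Integrative (phospho)proteome / drug-response analysis toolkit for cancer
cell-line panels. Starting from log10 intensity matrices (proteins and
phosphorylation sites x cell lines), set collections (pathways,
kinase->substrate maps) and drug-sensitivity matrices, it provides:

- **`syndata`** — seeded generator of synthetic panel data with planted
  ground truth: LFQ-like log10 intensities with intensity-dependent (MNAR)
  missingness, tissue-group covariance, correlated feature modules (one
  differential in a binary MSI-like phenotype), single-cell-line outliers,
  pathway/kinase activity shifts, linear drug markers and drug clusters
  sharing marker sets.
- **`core_io`** — TSV/GMT/annotation readers and writers, p-site -> 
  phosphoprotein aggregation (linear-scale summation), per-cell-line median
  centering, the pairwise-complete filter (default minimum 7 observations)
  and the linear fold-change convention `10**(high - low)`.
- **`stats`** — Pearson tests, an empirical-Bayes moderated t-test with
  moment-matched hyperparameters, one-sided hypergeometric enrichment,
  Benjamini–Hochberg adjustment and the RV matrix-correlation coefficient.
- **`activity`** — pathway and kinase activity scores (mean member
  z-scores integrated over protein-abundance / own-p-site / substrate
  channels), min–max relative activities in [0, 1], 2D activity landscapes
  (PCA embedding + Gaussian-kernel height fields) and per-cell-line
  waterfalls.
- **`modules_gba`** — unsigned WGCNA-style correlation-network modules
  (soft power, topological overlap, average linkage), three-axis
  set/module/phenotype association, guilt-by-association candidate
  annotations and protein-vs-phosphoprotein recapitulation overlap.
- **`outliers`** — single-cell-line high-abundance outlier calls
  (leave-one-out median, fold threshold, detection-only events) and
  Jaccard clustering of the outlier incidence matrix.
- **`drug_models`** — feature–drug Pearson screens, per-drug elastic nets
  with cross-validated 1-SE sparsity and marker-frequency ranking,
  exhaustive random-forest subset models for small metabolic panels and
  the regulatory-p-site screen.
- **`smbpls`** — sparse multiblock partial least squares: NIPALS
  components with soft-thresholded feature weights per block, nonnegative
  block combination weights and sparse drug weights, so each component
  yields a drug cluster plus its shared markers.
- **`cli`** — config-driven pipeline orchestration with checksummed
  manifests.

All intensities are log10 internally; missing values are explicit (never
zero); drug responses are canonicalized to "higher = more sensitive"
(GI50-like inputs are negated on ingest).

## Command line

```sh
# generate a synthetic panel with ground truth
phosphodrug simulate --out data/ --seed 1

# individual stages
phosphodrug aggregate --in data/psites.tsv --annotation data/annotation.tsv --out phospho.tsv
phosphodrug normalize --in data/protein.tsv --out protein_centered.tsv
phosphodrug activity --proteins data/protein.tsv --psites data/psites.tsv \
    --pathways data/pathways.gmt --kinases data/kinase_substrates.gmt \
    --annotation data/annotation.tsv --out activity/
phosphodrug modules --matrix data/protein.tsv --beta 6 --min-size 10 --out modules.tsv
phosphodrug outliers --matrix data/protein.tsv --fold 5 --out outliers.tsv
phosphodrug associate --features data/protein.tsv --drugs data/drugs.tsv --method corr --out markers.tsv
phosphodrug smbpls --blocks data/protein.tsv --blocks data/psites.tsv \
    --drugs data/drugs.tsv --components 2 --out clusters.tsv

# full pipeline from a YAML config
phosphodrug run --config pipeline.yaml
phosphodrug report --manifest out/manifest.json
```

A pipeline config names input paths, stage toggles and parameters:

```yaml
inputs:
  protein: data/protein.tsv
  psites: data/psites.tsv
  pathways: data/pathways.gmt
  kinase_substrates: data/kinase_substrates.gmt
  annotation: data/annotation.tsv
  drugs: data/drugs.tsv
  phenotype: data/phenotype.tsv
stages:
  smbpls: true
params:
  min_n: 7
  beta: 6.0
  threshold_fold: 5.0
  seed: 1
out_dir: out/
```

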