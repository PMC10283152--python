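# novatest

Detection of genes with **location-dependent noise variance** ("noisy" genes)
in spatial transcriptomics data.

Each gene's library-size-normalized, Anscombe-stabilized expression is
modeled as a function of spot coordinates with two Gaussian processes:

* a **homoscedastic GP** (constant-mean RBF kernel, constant noise variance),
  fitted by minimizing the negative log marginal likelihood; and
* an **approximate heteroscedastic GP** that keeps the homoscedastic
  posterior mean and refines only the variance, by fitting a second zero-mean
  GP to the per-spot variance residuals
  `z_i = (y_i − μ_GP,i)² − Σ_GP(i,i)` and combining
  `σ²_HGP = max(0, diag(Σ_GP) + μ_GPv)`.

The two models are compared by negative log predictive density (NLPD) on ten
random 90/10 train/validation splits; a one-sided Wilcoxon signed-rank test
(exact null distribution) with Benjamini–Hochberg FDR correction across genes
flags genes whose heteroscedastic NLPD is significantly lower. Detected genes
are clustered by their noise-variance patterns (Otsu binarization → Jaccard
distance → agglomerative clustering), and the patterns can be associated with
explanatory variables (cell-abundance proxy, marker-set enrichment /
cell-type heterogeneity) via Spearman correlation.

## Command line

```sh
# simulate a cohort (counts.tsv + coords.tsv + truth.tsv)
novatest simulate --spec spec.json --out sim/

# full pipeline: QC -> normalize -> noise test -> cluster -> explain
novatest run --counts sim/counts.tsv --coords sim/coords.tsv \
    --alpha 0.05 --repeats 10 --train-frac 0.9 --seed 1 --out results/

# re-cluster saved variance maps at a different k
novatest cluster --variance-maps results/variance_maps.tsv --k 3 --out reclust/
```

`novatest run` accepts dense TSV count matrices (spots × genes, first column
a spot id — ids of the form `12x34` encode coordinates directly) or
MatrixMarket triplets with sidecar gene/spot/coordinate files. Outputs are
TSVs (`results.tsv`, `qc_report.tsv`, `variance_maps.tsv`, `clusters.tsv`,
`representatives.tsv`, association tables) plus a `manifest.json` recording
the exact configuration; identical configurations reproduce identical
outputs.

## Package layout

| module | contents |
| --- | --- |
| `novatest.st_io` | count-matrix I/O, QC filtering, normalization + Anscombe |
| `novatest.gp_core` | RBF kernel, marginal likelihood + gradients, fitting, posterior |
| `novatest.hgp` | two-stage approximate heteroscedastic GP |
| `novatest.noise_test` | split plans, NLPD, Wilcoxon, BH-FDR, noisy-gene calling |
| `novatest.noise_cluster` | Otsu binarization, Jaccard distance, clustering |
| `novatest.explain` | cell abundance, marker enrichment, Spearman association |
| `novatest.sim_data` | synthetic coordinate grids, mean/variance fields, counts |
| `novatest.cli` | `novatest` command line and pipeline orchestration |
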