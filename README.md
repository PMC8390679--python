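# amniograph

Single-cell analysis pipeline for studying how an amnion-specific **ISL1**
gene-regulatory program supports mesoderm formation in primate embryos —
exercised end-to-end on a synthetic embryo atlas with full ground truth, so
every stage is testable without any external data download.

## Who this is for

Computational biologists who want a compact, fully reproducible
re-implementation of the bespoke single-cell procedures used in
peri-gastrulation embryo studies: ambient-RNA estimation via an exclusive
marker, regularized-NB differential expression with an empirical null band,
regulon-activity binarization, and graph-based pseudotime gene ranking —
each available as a library function, a CLI subcommand, and a tested unit.

## The methods at the core

- **Ambient RNA (exclusive-marker estimate).** Choriogonadotropin-like
  reporter genes are transcribed only by trophoblast, so any reporter UMI in
  epiblast cells is cell-free contamination. With ambient profile
  `b_g` (aggregate expression simplex) and cell depth `N_c`, the
  contaminated fraction is the Poisson MLE ratio
  `rho = sum(observed reporter counts) / sum(N_c * b_reporter)`, and
  correction subtracts `round(rho * N_c * b_g)` per entry (clamped at 0).
- **Normalization / DE.** A depth-offset negative-binomial model
  `mu_gc = N_c * p_g` with kernel-regularized per-gene dispersion `theta_g`
  yields Pearson residuals `z = (x - mu)/sqrt(mu + mu^2/theta)` clipped at
  `sqrt(n_cells)`. DE between groups uses two-tailed Welch's *t* on
  residuals, Benjamini–Hochberg FDR (cutoff 1%), and an empirical null band
  (99.9th percentile of |group mean difference| over 100 random cell
  partitions); significance requires both criteria.
- **Signature scoring.** A cell's score for a gene set is the set's share of
  the cell's total UMI, ×100 (additive, depth-invariant).
- **Pseudotime.** Geodesic distance from a root cell on the kNN graph of a
  PCA embedding, scaled to [0,1]; genes ranked by Moran's I
  `I = n/S0 * sum_ij w_ij z_i z_j / sum_i z_i^2` on the cell graph; the top
  100 are split into down/up dynamics clusters.
- **Regulon activity.** Per cell, genes are ranked by count (seeded random
  tie-breaks) and a regulon's recovery-curve AUC up to rank cutoff
  `k = ceil(5% of genes)` is computed; Hartigan's dip test picks the
  binarization rule (unimodal: mean + 2 sd; bimodal: KDE trough between the
  two main peaks); regulons active in <1% of cells are dropped.

## Worked example

```python
from amniograph import build_default_config, simulate_dataset, run_de, DeConfig
from amniograph.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=7))
print(report.summary["headline"])
# {'mesoderm_depleted_in_mutant': True,
#  'bmp4_down_in_mutant_amnion': True,
#  'isl1_regulon_amnion_specific': True}
print(round(report.summary["stages"]["ambient"]["rho_hat"], 3))   # 0.099
print(report.summary["composition"]["mesoderm_fraction_mt"])      # 0.024
print(report.summary["composition"]["mesoderm_fraction_wt"])      # 0.192
```

The run simulates 3000 cells (wild type + ISL1-mutant, 2000 genes, ambient
contamination 10%), recovers the contamination fraction (`rho_hat` 0.099 vs
a true 0.10), detects the mutant's compositional phenotype (mesoderm
collapses from 19% to 2% of cells while amnion expands), finds the BMP4-like
regulon target as the top down-regulated gene in mutant amnion, and calls
the ISL1 regulon bimodal with an amnion-pure active set.

The same stages are exposed on the command line:

```bash
amniograph simulate --seed 7 --out data/
amniograph qc --in data/ --min-genes 200 --out qc/
amniograph regulons --in qc/ --gmt data/regulons.gmt --out regulons/
amniograph run --seed 7 --out report/
```

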