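# m6apattern

Regulator-driven expression-pattern analysis for tumor cohorts:
resampling-based consensus clustering with automatic cluster-number
selection, single-sample gene-set enrichment (immune-cell,
stromal/immune and pathway signatures), empirical-Bayes moderated DEG
screening, univariate Cox filtering to a prognostic panel, a PCA-based
per-sample score (`m6ascore`) and its downstream survival / tumor
mutation burden / immune-checkpoint stratification. A synthetic-cohort
generator with planted clusters, latent hazard scores and burden
(anti-)correlation provides ground truth for every stage.

## Layout

| module | contents |
| --- | --- |
| `m6apattern.io` | TSV/MAF/GMT/CNV readers-writers, unit conversion (FPKM→TPM, log2) |
| `m6apattern.registry` | the 22-gene writer/reader/eraser registry; CNV & mutation frequency |
| `m6apattern.simulate` | synthetic cohorts + signature fixtures with known truth |
| `m6apattern.stats` | rank tests, Spearman, BH adjustment, checkpoint alias map |
| `m6apattern.consensus` | consensus clustering, CDF/delta-area k selection |
| `m6apattern.enrichment` | ssGSEA running-sum scoring, ESTIMATE-style stromal/immune scores |
| `m6apattern.differential` | moderated one-way ANOVA DEG screen, batch univariate Cox screen |
| `m6apattern.survival` | Kaplan–Meier, log-rank, Cox (Efron), optimal cutpoint, IPCW time-dependent AUC |
| `m6apattern.score` | PCA score, dichotomization, external validation, TMB & network integrations |
| `m6apattern.pipeline` / `m6apattern.cli` | end-to-end orchestration, YAML config, `m6apattern` CLI |

## CLI

```bash
# full pipeline on a synthetic cohort with planted 3-cluster structure
m6apattern run-all --preset planted --seed 7 --out run/
m6apattern summarize run/

# individual stages
m6apattern simulate --seed 1 --n-samples 150 --preset planted --out sim/
m6apattern cluster --expression sim/expression.tsv --n-resamples 500 --out cc/
m6apattern enrich --expression sim/expression.tsv --gmt sim/immune_cells.gmt --out scores.tsv
m6apattern deg --expression sim/expression.tsv --partition cc/partition.tsv --out deg.tsv
m6apattern cox-screen --expression sim/expression.tsv --clinical sim/clinical.tsv \
    --genes degs.tsv --out panel.tsv
m6apattern score --expression sim/expression.tsv --clinical sim/clinical.tsv \
    --panel panel.tsv --out score/
```

Exit codes: 0 ok, 2 config error, 3 data error, 4 numeric failure.
All outputs are plain TSV/JSON; `run-all` writes every intermediate
(cluster partitions, enrichment scores, DEG/Cox tables, score,
time-dependent AUC, TMB correlation) plus `report.json` next to the
resolved `config.yaml`. Identical seed + config reproduce byte-identical
outputs.

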