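# modelcongruence

Quantify how well candidate cancer models (cell lines, PDX, PDO) mimic a
target tumor subtype using bulk transcriptomics, and select the most
representative model. The workflow has three stages:

1. **Harmonize** tumor and model expression (quantile normalization,
   parametric empirical-Bayes batch correction, or a contrastive-PCA +
   mutual-nearest-neighbors aligner).
2. **Genome-wide pre-selection**: fit sparse discriminant analysis (optimal
   scoring with elastic-net penalties) on labeled tumors, project models
   onto the discriminant axis, and score each model by a robust deviance —
   the median/scaled-MAD standardized distance to the target cohort center —
   with a bootstrap CI and a normal-tail p-value, alongside the 1-D LDA
   assignment probability. Models pass when the assignment probability is
   high *and* the deviance p-value is large (congruence = no detectable
   difference).
3. **Pathway/gene scoring**: differential expression between the two tumor
   subtypes, preranked GSEA on log2 fold changes, pathway filtering (DE-gene
   count, size window, |NES| bound, user-pinned pathways), then per-pathway
   deviance scores (geometric mean of absolute per-gene median/MAD scores
   over the pathway's DE genes) with one-sided empirical p-values from a
   leave-one-out tumor null. Final ranking is the ascending mean pathway
   deviance over the unbiased selection set.

A synthetic-data module generates two-subtype cohorts plus candidate models
with planted congruence distances, pathway discordance, and batch effects,
so the whole pipeline is testable offline.

## CLI

Every stage is a subcommand of `modelcongruence`:

```sh
# generate a planted-truth scenario (TSV + GMT)
modelcongruence simulate --out-dir sim --seed 17

# stage by stage
modelcongruence harmonize --tumor sim/tumor.tsv --model sim/models.tsv \
    --method cpca_mnn --n-cpc 4 --mnn-k 5 --out-prefix aligned_
modelcongruence fit --tumor aligned_tumor.tsv --labels sim/annotations.tsv \
    --target subtypeA --lam 64 --seed 17 --out model.json
modelcongruence deviance --model model.json --tumor aligned_tumor.tsv \
    --cancer-models aligned_models.tsv --labels sim/annotations.tsv \
    --target subtypeA --bootstrap 1000 --seed 17 --out deviance.tsv
modelcongruence de --tumor aligned_tumor.tsv --labels sim/annotations.tsv \
    --target subtypeA --out de.tsv
modelcongruence gsea --de de.tsv --gmt sim/pathways.gmt --n-perm 10000 \
    --seed 17 --out gsea.tsv

# or everything at once from a YAML config
modelcongruence report --config run.yaml --out-dir out
```

`run.yaml` declares the inputs and per-stage parameters:

```yaml
target: subtypeA
input:
  tumor: sim/tumor.tsv          # genes x samples, log2 scale
  models: sim/models.tsv
  annotations: sim/annotations.tsv   # sample_id / source / class_label
  gmt: sim/pathways.gmt
  # external_de: de_table.tsv   # optional injected DE table
harmonize: {method: none}
sda: {gamma: 1.0e-3, lam: 64}   # lam: float = lasso weight, int = nonzero bound
deviance: {bootstrap: 1000, sigma_policy: mad}
gsea: {n_perm: 10000}
selection:
  p_sda_min: 0.5
  ds_pval_min: 0.05
  stringent_p_sda_min: 0.8
  stringent_ds_pval_min: 0.1
  pinned_models: []
  pinned_pathways: []
seed: 17
```

Outputs: `deviance.tsv`, `de.tsv`, `gsea.tsv`, `pathway_deviance.tsv`,
`gene_deviance.tsv`, and `report.json` (byte-identical across reruns with
the same config and seed).

## Package layout

| module | contents |
| --- | --- |
| `data_io` | `ExpressionMatrix`, annotations, GMT gene sets, TSV readers/writers |
| `harmonize` | quantile / EB-batch / cPCA+MNN correction |
| `sda` | optimal-scoring sparse discriminant solver, projection, 1-D LDA posterior, CV tuning |
| `deviance` | robust center/scale, genome-wide / gene / pathway deviance, bootstrap CI, empirical p-values |
| `de_gsea` | Welch and NB-Wald DE tests, preranked weighted-KS GSEA, pathway filters |
| `pipeline` | end-to-end orchestration, selection criteria, ranking, report emission |
| `synthetic` | planted-truth scenario generator and worked micro-fixture |
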