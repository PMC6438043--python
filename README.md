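# paritysig

Reusable, tested pipeline for detecting parity-associated gene-expression
signatures in normal breast tissue from probe-level microarray data:

- **preprocess** — present-call and CV probe filters, parametric
  empirical-Bayes (ComBat-style) batch adjustment, replicate QC via Lin's
  concordance correlation coefficient;
- **diffexpr** — vectorized per-probe OLS of log2 expression on parity with
  optional covariate adjustment (age, BMI, smoking duration, cycle/IUD),
  Storey q-values with smoother-based pi0 estimation;
- **discovery_validation** — stratified 2/3 discovery / 1/3 validation
  resampling (12 pairs by default): probes with discovery FDR < 20%,
  validation p < 0.05 and consistent direction in ≥ 2 pairs are selected;
- **tslp_patterns** — grouping of parous samples by time since last
  pregnancy (≤5 / 5–10 / >10 years), candidate selection (FDR < 10%,
  |FC| ≥ 1.2 in the overall or recent-pregnancy comparison), K-means
  clustering of fold-change profiles under the uncentered-Pearson distance,
  and rule-based classification into temporal patterns (transient,
  long-term changing, long-term constant, and two down patterns);
- **enrichment** — conditional hypergeometric term enrichment over an
  ontology DAG, rollup of enriched terms into broad
  developmental / immune / other categories, chi-squared association across
  clusters;
- **tissue_decomposition** — per-subject regression of whole-tissue
  expression on matched epithelium and stroma profiles, and the paired
  epithelium-vs-stroma comparison (paired t, BH FDR, median-ratio fold
  changes);
- **validation_stats** — RT-PCR delta-Ct / −ddCt fold changes with
  batch-adjusted significance, cross-platform ICC + Spearman concordance,
  group median ratios;
- **synthetic_data** — fully seeded generators (cohorts with TSLP strata and
  batch structure, expression with planted temporal patterns, presence
  calls, toy ontologies, tissue mixtures, Ct tables) so every stage is
  testable offline.

## CLI

Each stage is a subcommand whose outputs are valid inputs to the next:

```bash
paritysig simulate   --n-parous 79 --n-nulliparous 30 --n-probes 2000 --seed 1 --out sim/
paritysig preprocess --expr sim/expression.tsv --calls sim/calls.tsv --meta sim/metadata.tsv --out pre/
paritysig diffexpr   --expr pre/expression_adjusted.tsv --meta sim/metadata.tsv --out de.tsv
paritysig dvselect   --expr pre/expression_adjusted.tsv --meta sim/metadata.tsv --seed 1 --out dv/
paritysig patterns   --expr pre/expression_adjusted.tsv --meta sim/metadata.tsv --seed 1 --out pat/
paritysig enrich     --selection sel.txt --universe univ.txt --edges edges.tsv --annotation ann.tsv --out enr.tsv
paritysig decompose  --epithelium epi.tsv --stroma stroma.tsv --whole whole.tsv --out dec/
paritysig concordance --ct ct.tsv --meta sim/metadata.tsv --out fold.tsv
```

All matrices are tab-delimited, probes as rows and samples as columns.
Thresholds live in a YAML config (`--config`), defaulted to the study
values; every run logs the resolved configuration and seed.

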