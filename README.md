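# gwas2drug

Turn GWAS summary statistics into ranked drug-repurposing hypotheses.

Starting from per-SNP association results (effect size, standard error,
p-value — no individual-level genotypes), the pipeline:

1. **Gene-based association** — maps SNPs to genes with strand-aware windows
   (35 kb upstream / 10 kb downstream by default) and aggregates SNP z-scores
   into gene p-values while accounting for linkage disequilibrium (LD). Three
   models are computed: *mean* (sum of squared z, evaluated against its exact
   eigenvalue-mixture null via a chi-square series), *top* (smallest SNP
   p-value, calibrated by seeded simulation under the gene's LD matrix), and
   *multi* (a correlation-adjusted combination of the two). The extended MHC
   region (chr6:25–35 Mb) is flagged and excluded from downstream enrichment.
2. **Expression imputation (TWAS)** — combines SNP z-scores with
   expression-prediction weights to impute a signed gene-expression
   association Z per tissue, with tissues grouped into families (e.g.
   brain/blood) for reporting and network scoring.
3. **Drug gene-sets** — joins drug names to compound identifiers and ATC
   codes, merges records by ATC name, and builds one gene-set per drug at two
   evidence tiers: `annotation` (all reported targets) and `bioactivity`
   (binding-assay-backed targets only).
4. **Drug and class enrichment** — scores every drug gene-set by a
   competitive regression of gene association on set membership (controlling
   for SNP count and gene length), ranks drugs by −log10 p, and tests every
   ATC class at hierarchy levels 1–4 with a one-sided Mann–Whitney–Wilcoxon
   rank test (exact enumeration for small classes), reporting AUC,
   Bonferroni significance pooled across levels, and Benjamini–Hochberg
   q-values.
5. **Drug-target network** — exports a bipartite drug–gene graph (GraphML and
   JSON) with collapsed action annotations, tissue-family direction calls,
   and deterministic node ordering.

A seeded synthetic-study generator (AR(1) LD blocks, planted causal genes,
planted enriched ATC class, expression models with known directions) provides
ground-truth fixtures for every stage.

## Quick start

Write a config and run the full pipeline on a synthetic study:

```yaml
# config.yaml
seed: 11
outdir: out
n_sims: 5000
synth_params:
  n_genes: 300
  n_causal_genes: 20
  n_drugs: 100
  n_atc_classes: 10
  planted_class_size: 15
```

```sh
$ gwas2drug run --config config.yaml
{
  "class_bonferroni_threshold": 0.00125,
  "genome_wide_threshold": 0.000167,
  "n_classes_bonferroni": 4,
  "n_classes_fdr": 4,
  "n_classes_tested": 40,
  ...
  "n_significant_genes": 19,
  "n_snps": 2948,
  "top_class": "X",
  ...
}
```

The generator planted the ATC class `X17WY`; the class test recovers it at
every hierarchy level:

```sh
$ sort -t$'\t' -k7g out/class_enrichment.tsv | head -5
atc_code  level  n_in  n_out  U     auc  p_mww         bonferroni_sig  q_value
X         1      15    85     1275  1    3.895246e-10  True            3.895246e-09
X17       2      15    85     1275  1    3.895246e-10  True            3.895246e-09
X17W      3      15    85     1275  1    3.895246e-10  True            3.895246e-09
X17WY     4      15    85     1275  1    3.895246e-10  True            3.895246e-09
```

Outputs under `out/`: `gene_results.tsv`, `twas_results.tsv`,
`pathway_results.tsv`, `class_enrichment.tsv`, `gene_sets_annotation.gmt`,
`network.json`, `network.graphml`, `report.json`, and (for synthetic runs)
the generated inputs plus `truth.tsv` under `out/inputs/`.

Each stage is also available as its own subcommand (`synth`, `gene-assoc`,
`twas`, `drug-assoc`, `class-enrich`, `network`); `gwas2drug COMMAND --help`
lists the options. Re-running any stage with the same seed reproduces every
output file bit-for-bit.

## Input formats

All tables are tab-separated with a header row.

- **GWAS**: columns `snp, chrom, pos, a1, a2, beta, se, p, n`. Rows with
  non-positive `se`, `p` outside (0, 1], or missing fields are dropped with a
  logged reason; duplicate `(chrom, pos, a1, a2)` rows are an error.
- **Genes**: `gene_id, symbol, chrom, start, end, strand` (1-based inclusive
  span; strand `+`/`-`).
- **LD blocks** (`ld_blocks.txt`): a plain-text blockwise correlation format,

  ```text
  BLOCK <block_id> <k>
  SNPS <snp_1> ... <snp_k>
  <k rows of k whitespace-separated correlations>
  ```

  Matrices are symmetrized, must be positive semi-definite (tolerance 1e-8),
  and entries must lie in [−1, 1]. Lines starting with `#` are comments.
- **Expression models**: a weights table `gene_id, tissue, snp, weight` plus
  a covariance table holding each model's reference-panel SNP covariance
  (upper triangle).
- **Drug tables**: `interactions.tsv` (`drug_name, gene_id, action, source`),
  `name_to_cid.tsv` (`drug_name, cid`), `cid_to_atc.tsv` (`cid, atc_code`).
  Valid actions: `agonist, partial_agonist, antagonist, inverse_agonist,
  modulator, mixed_bioactivity, expr_up, expr_down, expr_mixed`; sources:
  `bioactivity` or `annotation`.

## Action collapse rules

When a drug–gene pair carries several interaction records, the network edge
keeps one action:

| records present | collapsed action |
| --- | --- |
| any bioactivity action + any `expr_*` | the bioactivity action (bioactivity outranks expression) |
| activating (`agonist`, `partial_agonist`) + inhibiting (`antagonist`, `inverse_agonist`) | `mixed_bioactivity` |
| same-direction bioactivity actions | the more specific term (`inverse_agonist` > `partial_agonist` > `agonist` = `antagonist` > `modulator`) |
| `expr_up` + `expr_down` (or any `expr_mixed`) | `expr_mixed` |

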