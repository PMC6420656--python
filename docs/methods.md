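# Methods

This note records the statistical models implemented in `gwas2drug`, the
default parameters and their rationale, the synthetic generator's scope, and
the numerical choices that matter for reproducing results.

## Gene-based association

SNPs are assigned to a gene when they fall inside the gene body extended by
an asymmetric window: 35 kb upstream and 10 kb downstream of transcription,
i.e. `[start − 35 kb, end + 10 kb]` on the plus strand and
`[start − 10 kb, end + 35 kb]` on the minus strand, boundaries inclusive.
The window captures proximal regulatory variation; `--ignore-strand` applies
the plus-strand convention everywhere. A SNP may map to several genes.

Within a gene, SNP z-scores (`beta/se`) are correlated through LD. Writing
`z ~ MVN(0, R)` under the null, with `R` the SNP correlation matrix from the
LD reference:

- **Mean model**: `T = Σ z_j²`, distributed as `Σ λ_j χ²₁` with `λ_j` the
  eigenvalues of `R`. The tail is evaluated exactly (see *Numerical
  choices*).
- **Top model**: the smallest two-sided SNP p-value, calibrated by `n_sims`
  seeded draws from `MVN(0, R)`; the reported p is
  `(1 + #{null ≤ observed}) / (n_sims + 1)`, so it is never 0 and has
  resolution `1/(n_sims + 1)` (default `n_sims = 10,000`).
- **Multi model**: the probit-transformed mean and top p-values are combined
  by a correlation-adjusted Stouffer rule,
  `p_multi = 1 − Φ((z_m + z_t) / √(2 + 2ρ))`, with `ρ` estimated from the
  same null draws (probit transforms of the Satterthwaite mean p and the
  empirical top p ranks). This keeps `p_multi` calibrated even though the
  two component statistics are strongly dependent.

Gene z-scores used downstream are `z_gene = Φ⁻¹(1 − p_multi)`, with p-values
floored at 1e-300 before the transform.

The extended MHC region (chromosome 6, 25–35 Mb, closed interval, gene body
overlap) is flagged; its genes are excluded from the competitive-test
universe because their exceptional LD and gene density otherwise dominate
set enrichment.

Bonferroni thresholds are reported at 3 significant figures (e.g.
`0.05/19,079 = 2.62e-6` genome-wide, `0.05/44,718 = 1.12e-6`
transcriptome-wide).

## Expression imputation

For an expression model with weights `w` over SNP set `l` and reference-panel
covariance `Γ`, the imputed expression association is

    z = Σ_l w_l (σ_l / σ_g) (β_l / se_l),   σ_g = √(wᵀ Γ w)

which is invariant to rescaling `w`. GWAS SNPs absent from the model are
dropped and `σ_g` recomputed over the retained SNPs; models left with no
SNPs, or with `σ_g = 0`, are skipped. Two-sided p-values use `2·Φ̄(|z|)`
(survival function, no far-tail cancellation). Tissues map to families
(e.g. brain/blood); direction tables report the signed calls per gene and
family.

## Drug gene-sets and enrichment

Drug names are canonicalized (lower case, collapsed whitespace), joined to
compound identifiers and then to ATC codes; records sharing an ATC name are
merged (union of identifiers, codes and interactions). Each drug yields a
gene-set at two evidence tiers: `annotation` (all interactions) and
`bioactivity` (assay-backed interactions only), intersected with the tested
gene universe.

**Competitive drug score.** For each set, gene `z_gene` is regressed on an
intercept, the set-membership indicator, and gene-size covariates (`n_snps`,
`log n_snps`, `length_bp`, `log length_bp`; collinear covariates are dropped
once per analysis). The drug p-value is the one-sided upper-tail t-test on
the indicator: it asks whether the drug's targets are *more* associated than
matched genes, not merely associated. Sets with fewer than 2 universe genes
are skipped; a response with no variance reports `beta = 0, p = 1`.

**Class enrichment.** Drugs are ranked by `−log10 p` and every ATC class at
hierarchy levels 1–4 (prefix widths 1, 3, 4, 5) with at least
`min_class_size = 5` ranked members is tested by a one-sided
Mann–Whitney–Wilcoxon test (alternative: class members rank higher). Ties
use midranks; `AUC = U/(n_in·n_out)` equals the pairwise-win fraction.
Multiple testing is handled across all levels pooled: Bonferroni at
`α / n_classes_tested` and Benjamini–Hochberg q-values side by side.

## Drug-target network

A bipartite graph over ranked drugs (optionally top `N`) and their target
genes. Gene nodes carry `target_score = z_gene + z_weight · max_tissue |z|`
(default `z_weight = 0.1`, family-restricted), tissue z-scores and direction
calls; edges carry the collapsed action (see README table) and evidence
source. `--bioactivity-only` keeps assay-backed edges; drugs left without
edges are dropped, and the bioactivity edge set is always a subset of the
full edge set. Node order, ranks and serialization are deterministic, so
fixed-seed exports are byte-identical.

## Synthetic generator

`SimulationConfig` defaults describe the reference study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 2000 | genes on 22 autosomes, disjoint bodies 1 Mb apart |
| `snps_per_gene` | (5, 15) | uniform SNP count per gene |
| `block_rho` | 0.5 | AR(1) LD within a gene: `R_ij = ρ^{i−j}` |
| `n_causal_genes` | 100 | genes given association signal (never in MHC) |
| `effect_z_mean` | 4.0 | mean shift of causal SNP z-scores |
| `n_drugs` / `n_atc_classes` | 300 / 25 | drug universe and ATC classes |
| `planted_class_size` | 20 | drugs in the enriched class |
| `planted_overlap` | 1.0 | fraction of planted drugs' targets drawn causal |
| `n_tissues` | 4 | expression models per gene (1–4 tissues) |
| GWAS `n` | 461,134 | reported per-SNP sample size |
| `se` | lognormal(log 0.02, 0.1) | per-SNP standard errors |

Per-stage random streams are spawned from `SeedSequence(seed, stage)`, so
adding a stage never perturbs another stage's draws. Ground truth (causal
genes, planted expression directions, planted class prefix and drugs) is
recorded in `truth.tsv`.

Realism and limits: LD is blockwise AR(1) within genes and zero between
genes — no long-range LD, no MAF structure, no allele-frequency–dependent
standard errors; effect sizes are a constant mean shift, not drawn from a
genetic architecture; the drug universe assigns 1–2 ATC codes and 2–8
targets per drug uniformly. The generator is built for calibration and
recovery testing, not for forecasting real-data power.

## Numerical choices

- **Eigenvalue-mixture tail** (`mixture_tail_p`): equal eigenvalues reduce
  exactly to a scaled chi-square. Otherwise the tail is computed by Ruben's
  chi-square series with `β = λ_min`: `P(Q > t) = Σ_j a_j P(χ²_{k+2j} >
  t/β)` with non-negative weights summing to 1, truncated when the residual
  mass is below `max(1e-12, 1e-6·p)` — a strict error bound, verified
  against Imhof numerical inversion to ~3e-9. Series coefficients are cached
  per eigenvalue vector (term cap 6000). Extreme eigenvalue spreads fall
  back to a Lugannani–Rice saddlepoint (excellent relative accuracy in the
  far tail, ~2–3% in the body — the reason it is not the primary method),
  then to the Satterthwaite moment match (`c = tr(R²)/k`, `f = k²/tr(R²)`),
  which is also exposed directly and is exact for equal eigenvalues.
- **Top-model null caching**: genes sharing a byte-identical LD matrix share
  one seeded null sample (stream seed mixes the user seed with a hash of
  `R`), making replicated simulations affordable without changing any
  single-gene result.
- **Exact MWW switch**: enumeration over `C(n, n_in)` label placements
  (midranks, ties included) replaces the normal approximation whenever
  `n ≤ 12` (≤ 924 placements). At such sizes no normal-family approximation
  tracks the discrete null closely (worst-case error ~0.03–0.06 for
  `n_in, n_out ≤ 6`), while just past the bound the tie- and
  continuity-corrected asymptotic p is already within ~0.007 of exact.
- **Serialization**: result tables print floats at 6 significant digits and
  p-like columns in scientific notation (round-trip to ~5e-6 relative); LD
  and fixture writers use 10 digits (round-trip to 1e-9). Network JSON is
  written with sorted keys and deterministic node order.
- **Seeds** are kept below 2³¹; all stochastic stages require an explicit
  seed.

## Limitations

- The LD reference must cover the GWAS SNPs; uncovered SNPs are dropped with
  a logged count rather than imputed.
- The competitive test assumes approximately Gaussian gene z-scores;
  extremely heavy-tailed inputs (e.g. unfloored p = 0) are clipped rather
  than modeled.
- ATC classes are tested per level with pooled multiple-testing correction;
  hierarchical dependence between a class and its parent is not modeled.
- Expression models are linear in SNP dosage with a fixed reference
  covariance; no cross-tissue borrowing or colocalization testing.
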