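"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the inputs of a summary-statistic
drug-repurposing study: blockwise LD (one AR(1) block per gene, zero
cross-gene LD), per-SNP z-scores drawn from the block's multivariate normal
with a planted mean shift on causal genes, sparse expression-weight models
whose sign is aligned with the planted shift for causal genes, and a drug
database whose designated "planted" therapeutic class preferentially
targets causal genes. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .io_formats import (GeneAnnotation, LDReference, SnpStat, write_genes,
                         write_gwas, write_ld, write_tiers)
from .twas import ExpressionModel, write_expression_models

ACTIONS_EXPR = ("expr_up", "expr_down", "expr_mixed")
ACTIONS_BIO = ("agonist", "partial_agonist", "antagonist", "modulator",
               "inverse_agonist", "mixed_bioactivity")
ACTIONS = ACTIONS_EXPR + ACTIONS_BIO

_STUDY_N = 461_134  # cases + controls of the emulated case-control GWAS


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    ``effect_z_mean`` is the mean non-centrality added to every SNP z-score
    of a causal gene; ``planted_overlap`` is the fraction of each
    planted-class drug's targets drawn from causal genes.
    """

    seed: int = 0
    n_genes: int = 2000
    snps_per_gene: tuple[int, int] = (5, 15)
    block_rho: float = 0.5
    n_causal_genes: int = 100
    effect_z_mean: float = 4.0
    n_drugs: int = 300
    targets_per_drug: tuple[int, int] = (2, 8)
    n_atc_classes: int = 25
    planted_class_size: int = 20
    planted_overlap: float = 1.0
    n_tissues: int = 4
    weights_per_gene: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        if not (0.0 <= self.planted_overlap <= 1.0):
            raise ValueError("planted_overlap must be in [0, 1]")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        if self.planted_class_size > self.n_drugs:
            raise ValueError("planted_class_size cannot exceed n_drugs")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class GroundTruth:
    """What was planted: the answer key for power checks."""

    causal_genes: list[str]
    expr_direction: dict[str, int]  # causal gene -> +1 / -1
    planted_class_prefix: str
    planted_drugs: list[str]


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def simulate_genes(config: SimulationConfig) -> list[GeneAnnotation]:
    """Gene bodies laid out over 22 autosomes, 1 Mb apart (no overlap).

    Genes landing in chr6:25-35 Mb exercise the MHC exclusion downstream.
    """
    rng = config.rng(0)
    genes = []
    for i in range(config.n_genes):
        chrom = str((i % 22) + 1)
        start = (i // 22) * 1_000_000 + 1_000_000
        length = int(rng.integers(5_000, 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(
            gene_id=_gene_id(i), symbol=f"SYM{i:05d}", chrom=chrom,
            start=start, end=start + length, strand=strand,
        ))
    return genes


def ar1_correlation(k: int, rho: float) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld(config: SimulationConfig) -> LDReference:
    """One AR(1) LD block per gene; cross-gene LD is zero by construction."""
    rng = config.rng(1)
    lo, hi = config.snps_per_gene
    blocks = []
    for i in range(config.n_genes):
        k = int(rng.integers(lo, hi + 1))
        ids = [f"{_gene_id(i)}_s{j}" for j in range(k)]
        blocks.append((ids, ar1_correlation(k, config.block_rho)))
    return LDReference(blocks=blocks, provenance=f"synthetic AR(1) rho={config.block_rho}")


def pick_causal_genes(config: SimulationConfig,
                      genes: list[GeneAnnotation]) -> tuple[list[str], dict[str, int]]:
    """Causal genes drawn outside the MHC (chr6:25-35 Mb), with a planted
    expression direction each."""
    rng = config.rng(2)
    eligible = [g.gene_id for g in genes
                if not (g.chrom == "6" and g.start <= 35_000_000 and g.end >= 25_000_000)]
    causal = sorted(rng.choice(eligible, size=config.n_causal_genes, replace=False))
    directions = {g: int(d) for g, d in zip(causal, rng.choice([-1, 1], size=len(causal)))}
    return list(causal), directions


def simulate_gwas(config: SimulationConfig, ld: LDReference,
                  genes: list[GeneAnnotation],
                  causal_genes: list[str]) -> list[SnpStat]:
    """Per-block z ~ MVN(shift, R); p two-sided; beta = z * se, se log-normal.

    Causal genes receive mean shift ``effect_z_mean`` on every SNP z.
    SNP positions are spread evenly inside the gene body so window mapping
    recovers the block structure.
    """
    rng = config.rng(3)
    causal = set(causal_genes)
    by_id = {g.gene_id: g for g in genes}
    alleles = np.array(list("ACGT"))
    out: list[SnpStat] = []
    chol_cache: dict[int, np.ndarray] = {}
    for ids, R in ld.blocks:
        gene = by_id[ids[0].rsplit("_s", 1)[0]]
        k = len(ids)
        L = chol_cache.get(k)
        if L is None:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
            chol_cache[k] = L
        z = L @ rng.standard_normal(k)
        if gene.gene_id in causal:
            z = z + config.effect_z_mean
        se = np.exp(rng.normal(np.log(0.02), 0.1, size=k))
        p = 2.0 * stats.norm.sf(np.abs(z))
        pos = np.linspace(gene.start, gene.end, k).astype(int)
        for j, sid in enumerate(ids):
            a = rng.choice(4, size=2, replace=False)
            out.append(SnpStat(
                snp_id=sid, chrom=gene.chrom, pos=int(pos[j]),
                a1=str(alleles[a[0]]), a2=str(alleles[a[1]]),
                beta=float(z[j] * se[j]), se=float(se[j]),
                p=float(min(p[j], 1.0)), n=_STUDY_N,
            ))
    return out


def simulate_expression_models(config: SimulationConfig, causal_genes: list[str],
                               ld: LDReference, expr_direction: dict[str, int],
                               ) -> list[ExpressionModel]:
    """Sparse per-gene, per-tissue weight vectors over the gene's own SNPs.

    Causal genes get all weights signed by their planted direction, so the
    imputed Z inherits that sign under the planted z shift; other genes get
    random signs. Reference genotypes are standardized (unit variance), so
    the reference covariance is the gene's LD block restricted to model SNPs.
    """
    rng = config.rng(4)
    causal = set(causal_genes)
    tissues = [f"tissue{t}" for t in range(config.n_tissues)]
    lo, hi = config.weights_per_gene
    models = []
    for ids, R in ld.blocks:
        gene = ids[0].rsplit("_s", 1)[0]
        n_t = int(rng.integers(1, config.n_tissues + 1))
        gene_tissues = sorted(rng.choice(config.n_tissues, size=n_t, replace=False))
        for t in gene_tissues:
            m = min(int(rng.integers(lo, hi + 1)), len(ids))
            sel = np.sort(rng.choice(len(ids), size=m, replace=False))
            mags = rng.uniform(0.1, 1.0, size=m)
            if gene in causal:
                w = expr_direction[gene] * mags
            else:
                w = rng.choice([-1, 1], size=m) * mags
            if np.allclose(w, 0):
                continue  # degenerate model would be unusable downstream
            order = [ids[j] for j in sel]
            cov = R[np.ix_(sel, sel)]
            models.append(ExpressionModel(
                gene_id=gene, tissue=tissues[t], snp_order=order,
                weights={s: float(v) for s, v in zip(order, w)},
                ref_var={s: 1.0 for s in order}, ref_cov=cov,
            ))
    return models


def _atc_prefixes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Distinct 5-character ATC level-4 prefixes (L DD L L)."""
    letters = string.ascii_uppercase
    prefixes: list[str] = []
    seen = set()
    while len(prefixes) < config.n_atc_classes:
        p = (letters[rng.integers(0, 26)] + f"{rng.integers(0, 100):02d}"
             + letters[rng.integers(0, 26)] + letters[rng.integers(0, 26)])
        if p not in seen:
            seen.add(p)
            prefixes.append(p)
    return prefixes


def simulate_drug_database(config: SimulationConfig, causal_genes: list[str],
                           all_genes: list[str]):
    """Drug-gene interactions plus name->CID and CID->ATC mapping tables.

    Returns (interactions, name_to_cid, cid_to_atc, truth_class_prefix,
    planted_drug_names). Planted-class drugs draw a ``planted_overlap``
    fraction of their targets from causal genes; everyone else draws
    uniformly from the gene universe.
    """
    import pandas as pd

    rng = config.rng(5)
    causal = list(causal_genes)
    noncausal = sorted(set(all_genes) - set(causal))
    prefixes = _atc_prefixes(config, rng)
    planted_prefix = prefixes[0]
    lo, hi = config.targets_per_drug

    inter_rows, cid_rows, atc_rows = [], [], []
    planted_names = []
    next_cid = 10_000
    for d in range(config.n_drugs):
        name = f"drug{d:04d}"
        is_planted = d < config.planted_class_size
        if is_planted:
            planted_names.append(name)
            codes = [planted_prefix + f"{rng.integers(0, 100):02d}"]
        else:
            n_codes = 1 + int(rng.random() < 0.2)
            ks = rng.choice(np.arange(1, len(prefixes)), size=n_codes, replace=False)
            codes = [prefixes[k] + f"{rng.integers(0, 100):02d}" for k in ks]
        n_cids = 1 + int(rng.random() < 0.3)
        cids = list(range(next_cid, next_cid + n_cids))
        next_cid += n_cids
        for c in cids:
            cid_rows.append((name, c))
        for c, code in zip(np.resize(cids, len(codes)), codes):
            atc_rows.append((int(c), code))

        n_targets = int(rng.integers(lo, hi + 1))
        if is_planted:
            n_causal_t = int(round(config.planted_overlap * n_targets))
            t_causal = rng.choice(causal, size=min(n_causal_t, len(causal)), replace=False)
            n_rest = n_targets - len(t_causal)
            t_rest = rng.choice(noncausal, size=n_rest, replace=False) if n_rest else []
            targets = list(t_causal) + list(t_rest)
        else:
            targets = list(rng.choice(all_genes, size=n_targets, replace=False))
        for g in targets:
            if rng.random() < 0.7:
                action = ACTIONS_BIO[rng.integers(0, len(ACTIONS_BIO))]
                source = "bioactivity" if rng.random() < 0.8 else "annotation"
            else:
                action = ACTIONS_EXPR[rng.integers(0, len(ACTIONS_EXPR))]
                source = "annotation"
            inter_rows.append((name, g, action, source))

    interactions = pd.DataFrame(inter_rows, columns=["drug_name", "gene_id", "action", "source"])
    name_to_cid = pd.DataFrame(cid_rows, columns=["drug_name", "cid"])
    cid_to_atc = pd.DataFrame(atc_rows, columns=["cid", "atc_code"])
    return interactions, name_to_cid, cid_to_atc, planted_prefix, planted_names


def simulate_tiers(config: SimulationConfig, all_genes: list[str]) -> dict[str, str]:
    """~30% of genes tagged druggable, split across the three tiers."""
    rng = config.rng(6)
    tiers = {}
    for g in all_genes:
        u = rng.random()
        if u < 0.10:
            tiers[g] = "T1"
        elif u < 0.20:
            tiers[g] = "T2"
        elif u < 0.30:
            tiers[g] = "T3"
    return tiers


@dataclass
class SyntheticStudy:
    """A complete generated study: every pipeline input plus the answer key."""

    config: SimulationConfig
    genes: list[GeneAnnotation]
    ld: LDReference
    snps: list[SnpStat]
    models: list[ExpressionModel]
    interactions: "object"
    name_to_cid: "object"
    cid_to_atc: "object"
    tiers: dict[str, str]
    truth: GroundTruth
    families: dict[str, str] = field(default_factory=dict)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every input table for one synthetic study, deterministically."""
    genes = simulate_genes(config)
    ld = simulate_ld(config)
    causal, directions = pick_causal_genes(config, genes)
    snps = simulate_gwas(config, ld, genes, causal)
    models = simulate_expression_models(config, causal, ld, directions)
    gene_ids = [g.gene_id for g in genes]
    inter, n2c, c2a, prefix, planted = simulate_drug_database(config, causal, gene_ids)
    tiers = simulate_tiers(config, gene_ids)
    # first half of tissues "brain", rest "blood" — mirrors a CNS-family run
    fams = {f"tissue{t}": ("brain" if t < (config.n_tissues + 1) // 2 else "blood")
            for t in range(config.n_tissues)}
    truth = GroundTruth(causal_genes=causal, expr_direction=directions,
                        planted_class_prefix=prefix, planted_drugs=planted)
    return SyntheticStudy(config=config, genes=genes, ld=ld, snps=snps,
                          models=models, interactions=inter, name_to_cid=n2c,
                          cid_to_atc=c2a, tiers=tiers, truth=truth, families=fams)


def write_fixture(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory in the formats io_formats reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": out / "gwas.tsv", "genes": out / "genes.tsv",
        "ld": out / "ld_blocks.txt", "tiers": out / "tiers.tsv",
        "weights": out / "expr_weights.tsv", "cov": out / "expr_cov.tsv",
        "interactions": out / "interactions.tsv",
        "name_to_cid": out / "name_to_cid.tsv",
        "cid_to_atc": out / "cid_to_atc.tsv",
        "truth": out / "truth.tsv", "families": out / "families.yaml",
    }
    write_gwas(study.snps, paths["gwas"])
    write_genes(study.genes, paths["genes"])
    write_ld(study.ld, paths["ld"])
    write_tiers(study.tiers, paths["tiers"])
    write_expression_models(study.models, paths["weights"], paths["cov"])
    study.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    study.name_to_cid.to_csv(paths["name_to_cid"], sep="\t", index=False)
    study.cid_to_atc.to_csv(paths["cid_to_atc"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"planted_class_prefix\t{study.truth.planted_class_prefix}\n")
        for g in study.truth.causal_genes:
            fh.write(f"causal_gene\t{g}:{study.truth.expr_direction[g]:+d}\n")
        for d in study.truth.planted_drugs:
            fh.write(f"planted_drug\t{d}\n")
    import yaml
    with open(paths["families"], "w") as fh:
        yaml.safe_dump({"families": study.families}, fh)
    return paths
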