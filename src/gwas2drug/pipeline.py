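"""End-to-end orchestration: synthetic inputs (optional) -> gene association
-> expression imputation -> drug sets -> class enrichment -> network.

Every stage persists its table under the configured output directory and the
run ends with a JSON summary report. Stage outputs are pure functions of
(inputs, config): re-running with the same seed reproduces every file
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import drugsets, enrichment, gene_assoc, io_formats, network, synth, twas

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One YAML document drives the whole run; ``seed`` is mandatory because
    the top-SNP gene model and the synthetic generator are stochastic."""

    seed: int
    outdir: str = "out"
    synth_params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    up_kb: float = 35.0
    down_kb: float = 10.0
    mhc_chrom: str = "6"
    mhc_lo_bp: int = 25_000_000
    mhc_hi_bp: int = 35_000_000
    n_sims: int = 10_000
    alpha: float = 0.05
    tier: str = "annotation"
    min_class_size: int = 5
    families: dict = field(default_factory=dict)
    family: str = "brain"
    z_weight: float = 0.1
    top_drugs: int | None = 20
    bioactivity_only: bool = False
    ignore_strand: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages present)")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        if self.synth_params:
            return
        required = ["gwas", "genes", "ld", "tiers", "weights", "cov",
                    "interactions", "name_to_cid", "cid_to_atc"]
        missing = [k for k in required
                   if k not in self.inputs or not Path(self.inputs[k]).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the summary report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_inputs()
    report: dict = {"seed": config.seed}

    # ---- inputs (generated or read) ------------------------------------
    if config.synth_params:
        sim = synth.SimulationConfig(seed=config.seed, **config.synth_params)
        study = synth.simulate_study(sim)
        synth.write_fixture(study, out / "inputs")
        snps, genes, ld = study.snps, study.genes, study.ld
        tiers = study.tiers
        models = study.models
        interactions = study.interactions
        name_to_cid, cid_to_atc = study.name_to_cid, study.cid_to_atc
        families = config.families or study.families
        report["synthetic"] = True
    else:
        import pandas as pd
        snps = io_formats.read_gwas(config.inputs["gwas"])
        genes = io_formats.read_genes(config.inputs["genes"])
        ld = io_formats.read_ld(config.inputs["ld"])
        tiers = io_formats.read_tiers(config.inputs["tiers"])
        models = twas.read_expression_models(config.inputs["weights"], config.inputs["cov"])
        interactions = pd.read_csv(config.inputs["interactions"], sep="\t")
        name_to_cid = pd.read_csv(config.inputs["name_to_cid"], sep="\t")
        cid_to_atc = pd.read_csv(config.inputs["cid_to_atc"], sep="\t")
        families = config.families
        if not families and "families" in config.inputs:
            families = yaml.safe_load(Path(config.inputs["families"]).read_text())["families"]
        report["synthetic"] = False
    report["n_snps"] = len(snps)
    report["n_genes_annotated"] = len(genes)

    # ---- gene-based association ----------------------------------------
    gene_results = gene_assoc.run_gene_assoc(
        snps, genes, ld, tiers, up_kb=config.up_kb, down_kb=config.down_kb,
        n_sims=config.n_sims, seed=config.seed, ignore_strand=config.ignore_strand)
    io_formats.write_results_table(gene_results, out / "gene_results.tsv")
    n_tested = len(gene_results)
    thr_gene = gene_assoc.bonferroni_threshold(config.alpha, max(n_tested, 1))
    sig = [r for r in gene_results if r.p_multi <= thr_gene]
    sig_out = [r for r in sig if not r.in_mhc]
    report.update(
        n_genes_tested=n_tested,
        genome_wide_threshold=thr_gene,
        n_significant_genes=len(sig),
        n_significant_outside_mhc=len(sig_out),
        n_druggable_significant=sum(1 for r in sig_out if r.tier != "none"),
    )
    log.info("gene_assoc: %d genes tested, %d significant (%d outside MHC)",
             n_tested, len(sig), len(sig_out))

    # ---- expression imputation ------------------------------------------
    twas_results = twas.run_twas(models, snps, families=families)
    io_formats.write_results_table(twas_results, out / "twas_results.tsv")
    thr_twas = (twas.transcriptome_threshold(config.alpha, len(twas_results))
                if twas_results else None)
    report.update(n_twas_associations=len(twas_results),
                  transcriptome_threshold=thr_twas)

    # ---- drug records and gene-sets -------------------------------------
    drug_names = sorted(interactions["drug_name"].astype(str).unique())
    records = drugsets.map_drugs_to_atc(drug_names, name_to_cid, cid_to_atc)
    records = drugsets.attach_interactions(records, interactions)
    records = drugsets.merge_by_atc_name(records)
    universe = {g.gene_id for g in genes}
    sets = drugsets.build_gene_sets(records, tier=config.tier, universe=universe)
    drugsets.write_gmt(sets, out / f"gene_sets_{config.tier}.gmt")
    report.update(n_drugs=len(records), n_gene_sets=len(sets),
                  n_distinct_gene_sets=len({s.gene_ids for s in sets}))

    # ---- enrichment ------------------------------------------------------
    pathway = enrichment.run_pathway_analysis(gene_results, sets)
    with_atc = {r.atc_name for r in records if r.atc_codes}
    pathway_atc = [p for p in pathway if p.set_id.split("|")[0] in with_atc]
    io_formats.write_results_table(pathway, out / "pathway_results.tsv")
    ranked = [(sid.split("|")[0], score)
              for sid, score in enrichment.rank_drugs(pathway_atc)]
    classes, n_classes = enrichment.test_all_classes(
        ranked, records, min_class_size=config.min_class_size, alpha=config.alpha)
    io_formats.write_results_table(classes, out / "class_enrichment.tsv")
    report.update(
        n_drugs_ranked=len(ranked),
        n_classes_tested=n_classes,
        class_bonferroni_threshold=(config.alpha / n_classes if n_classes else None),
        n_classes_bonferroni=sum(1 for c in classes if c.bonferroni_sig),
        n_classes_fdr=sum(1 for c in classes if c.q_value < config.alpha),
        top_class=(min(classes, key=lambda c: (c.p_mww, c.atc_code)).atc_code
                   if classes else None),
    )

    # ---- network ---------------------------------------------------------
    graph = network.build_network(
        ranked, gene_results, twas_results, records, family=config.family,
        families=families, bioactivity_only=config.bioactivity_only,
        z_weight=config.z_weight, top_drugs=config.top_drugs)
    network.export_network(graph, out / "network.json", format="json")
    network.export_network(graph, out / "network.graphml", format="graphml")
    n_drug_nodes = sum(1 for _, d in graph.nodes(data=True) if d["bipartite"] == 0)
    report.update(network_drug_nodes=n_drug_nodes,
                  network_gene_nodes=graph.number_of_nodes() - n_drug_nodes,
                  network_edges=graph.number_of_edges())

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
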