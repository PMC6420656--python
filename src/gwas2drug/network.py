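"""Phenotype-scored bipartite drug-target networks.

Drug nodes carry the drug's pathway association in -log10(p) units and are
ranked by it; target nodes carry the gene-based association score plus
imputed-expression Z per tissue of the chosen family, combined into an
ordering score (gene score dominates, expression refines). Edges carry one
of the nine interaction types; conflicting records for one (drug, gene)
pair collapse to the mixed category of their kind.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx

from .drugsets import ACTION_VOCAB, DrugRecord
from .gene_assoc import GeneResult
from .twas import TwasResult

log = logging.getLogger(__name__)

EXPR_ACTIONS = {"expr_up", "expr_down", "expr_mixed"}
ACTIVATING = {"agonist", "partial_agonist"}
INHIBITING = {"antagonist", "inverse_agonist"}
# among same-direction bioactivity records the more specific term wins
_BIO_SPECIFICITY = {"inverse_agonist": 5, "partial_agonist": 4,
                    "agonist": 3, "antagonist": 3, "modulator": 1}


def collapse_actions(actions: set[str]) -> str:
    """Collapse conflicting action annotations into one edge type.

    Bioactivity evidence outranks expression evidence. Mixed activating and
    inhibiting records (or an explicit mixed record) give the mixed category
    of their kind; otherwise the most specific term wins.
    """
    bad = actions - ACTION_VOCAB
    if bad:
        raise ValueError(f"unknown action(s): {sorted(bad)}")
    bio = actions - EXPR_ACTIONS
    if bio:
        if "mixed_bioactivity" in bio or (bio & ACTIVATING and bio & INHIBITING):
            return "mixed_bioactivity"
        return max(bio, key=lambda a: (_BIO_SPECIFICITY[a], a))
    if "expr_mixed" in actions or ("expr_up" in actions and "expr_down" in actions):
        return "expr_mixed"
    return next(iter(actions))


def target_score(magma_score: float, tissue_z: dict[str, float],
                 z_weight: float = 0.1) -> float:
    """Combined target ordering score: gene score plus a weighted maximum
    |Z| over the family's tissues (0 when the gene has no model)."""
    zmax = max((abs(z) for z in tissue_z.values()), default=0.0)
    return magma_score + z_weight * zmax


def build_network(ranked_drugs: list[tuple[str, float]],
                  gene_results: list[GeneResult],
                  twas_results: list[TwasResult],
                  records: list[DrugRecord],
                  family: str = "brain",
                  families: dict[str, str] | None = None,
                  bioactivity_only: bool = False,
                  z_weight: float = 0.1,
                  top_drugs: int | None = None) -> nx.Graph:
    """Assemble the bipartite graph from the three upstream result tables.

    ``ranked_drugs`` is (drug name, -log10 p) in rank order; ``top_drugs``
    caps the drug side and genes follow from surviving edges. With
    ``bioactivity_only``, expression-type records are excluded before edge
    collapsing; drugs left without edges are dropped with a log entry.
    """
    families = families or {}
    import math

    if top_drugs is not None:
        ranked_drugs = ranked_drugs[:top_drugs]
    drug_scores = dict(ranked_drugs)
    rec_by_name = {r.atc_name: r for r in records}
    magma = {r.gene_id: -math.log10(max(r.p_multi, 1e-300)) for r in gene_results}
    fam_z: dict[str, dict[str, float]] = {}
    for t in twas_results:
        if families.get(t.tissue, t.family) == family or t.family == family:
            fam_z.setdefault(t.gene_id, {})[t.tissue] = t.z

    g = nx.Graph()
    edges = []
    for name, _score in ranked_drugs:
        rec = rec_by_name.get(name)
        if rec is None:
            continue
        per_gene: dict[str, list] = {}
        for it in rec.interactions:
            if bioactivity_only and it.action in EXPR_ACTIONS:
                continue
            per_gene.setdefault(it.gene_id, []).append(it)
        if not per_gene:
            log.info("build_network: drug %s has no surviving edges; dropped", name)
            continue
        for gene, its in sorted(per_gene.items()):
            action = collapse_actions({i.action for i in its})
            evidence = ("bioactivity" if any(i.source_set == "bioactivity" for i in its)
                        else "annotation")
            edges.append((name, gene, action, evidence))

    drug_names = sorted({d for d, *_ in edges})
    gene_names = sorted({g_ for _, g_, *_ in edges})
    drug_order = sorted(drug_names, key=lambda n: (-drug_scores.get(n, 0.0), n))
    for rank, name in enumerate(drug_order, start=1):
        g.add_node(f"drug::{name}", bipartite=0, kind="drug", label=name,
                   score=float(drug_scores.get(name, 0.0)), rank=rank)
    scored = []
    for gene in gene_names:
        tz = fam_z.get(gene, {})
        scored.append((gene, magma.get(gene, 0.0), tz,
                       target_score(magma.get(gene, 0.0), tz, z_weight)))
    gene_order = sorted(scored, key=lambda t: (-t[3], t[0]))
    for rank, (gene, ms, tz, cs) in enumerate(gene_order, start=1):
        g.add_node(f"gene::{gene}", bipartite=1, kind="gene", label=gene,
                   magma_score=float(ms), combined_score=float(cs), rank=rank,
                   tissue_z=";".join(f"{t}={tz[t]:+.4f}" for t in sorted(tz)),
                   directions=";".join(f"{t}={'+' if tz[t] >= 0 else '-'}"
                                       for t in sorted(tz)))
    for drug, gene, action, evidence in sorted(edges):
        g.add_edge(f"drug::{drug}", f"gene::{gene}", action=action, evidence=evidence)
    return g


def export_network(graph: nx.Graph, path: str | Path, format: str = "json") -> None:
    """Serialize the network deterministically as GraphML or node-link JSON."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json":
        data = nx.node_link_data(graph, edges="links")
        data["nodes"] = sorted(data["nodes"], key=lambda n: n["id"])
        data["links"] = sorted(data["links"], key=lambda e: (e["source"], e["target"]))
        path.write_text(json.dumps(data, sort_keys=True, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network_json(path: str | Path) -> nx.Graph:
    data = json.loads(Path(path).read_text())
    return nx.node_link_graph(data, edges="links")
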