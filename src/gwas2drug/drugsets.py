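"""Assemble drug records, ATC mappings and gene-sets for enrichment.

Drug names are mapped to compound identifiers (CIDs) and on to ATC codes,
then merged by canonical (ATC) name — one drug record may carry several CIDs
and codes. Each drug yields a gene-set per evidence tier: the *annotation*
tier uses every collected interaction, the *bioactivity* tier only curated
binding evidence. Drugs without an ATC code still produce gene-sets but are
excluded from therapeutic-class enrichment.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ConsistencyError, DruggabilityTier, FormatError

log = logging.getLogger(__name__)

ACTION_VOCAB = frozenset({
    "expr_up", "expr_down", "expr_mixed",
    "agonist", "partial_agonist", "antagonist", "modulator",
    "inverse_agonist", "mixed_bioactivity",
})
SOURCE_VOCAB = frozenset({"annotation", "bioactivity"})

# L DD L L DD, with class-level prefixes (1, 3, 4 or 5 characters) allowed
_ATC_RE = re.compile(r"^[A-Z]($|\d{2}($|[A-Z]($|[A-Z]($|\d{2}$))))")


def valid_atc(code: str) -> bool:
    """Syntactic ATC check only (no dictionary lookup)."""
    return bool(_ATC_RE.match(code))


@dataclass(frozen=True)
class Interaction:
    gene_id: str
    action: str
    source_set: str

    def __post_init__(self) -> None:
        if self.action not in ACTION_VOCAB:
            raise FormatError(f"unknown action {self.action!r}")
        if self.source_set not in SOURCE_VOCAB:
            raise FormatError(f"unknown source set {self.source_set!r}")


@dataclass
class DrugRecord:
    """A drug after ATC-name merging: CIDs, codes and typed interactions."""

    atc_name: str
    cids: set[int] = field(default_factory=set)
    atc_codes: set[str] = field(default_factory=set)
    interactions: list[Interaction] = field(default_factory=list)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    gene_ids: frozenset[str]


def canonical_name(name: str) -> str:
    """Case-insensitive matching with whitespace normalization."""
    return " ".join(name.strip().lower().split())


def map_drugs_to_atc(names: list[str], name_to_cid: pd.DataFrame,
                     cid_to_atc: pd.DataFrame) -> list[DrugRecord]:
    """Build record skeletons: name -> all CIDs -> all ATC codes.

    Drugs with no ATC code are retained (flagged via empty atc_codes) so
    they can still contribute gene-sets.
    """
    if name_to_cid.empty or cid_to_atc.empty:
        raise ConsistencyError("empty drug mapping table(s)")
    n2c: dict[str, set[int]] = {}
    for r in name_to_cid.itertuples():
        n2c.setdefault(canonical_name(str(r.drug_name)), set()).add(int(r.cid))
    c2a: dict[int, set[str]] = {}
    for r in cid_to_atc.itertuples():
        code = str(r.atc_code)
        if not valid_atc(code):
            raise FormatError(f"syntactically invalid ATC code {code!r}")
        c2a.setdefault(int(r.cid), set()).add(code)
    records = []
    n_unmapped = 0
    for name in names:
        cname = canonical_name(name)
        cids = n2c.get(cname, set())
        codes = set().union(*(c2a.get(c, set()) for c in cids)) if cids else set()
        if not codes:
            n_unmapped += 1
        records.append(DrugRecord(atc_name=cname, cids=set(cids), atc_codes=codes))
    if n_unmapped:
        log.info("map_drugs_to_atc: %d drug(s) without ATC code "
                 "(kept for gene-sets, excluded from class enrichment)", n_unmapped)
    return records


def merge_by_atc_name(records: list[DrugRecord]) -> list[DrugRecord]:
    """Union cids/codes/interactions of records sharing a canonical name;
    exact duplicate interactions collapse. Idempotent."""
    merged: dict[str, DrugRecord] = {}
    for r in records:
        tgt = merged.get(r.atc_name)
        if tgt is None:
            merged[r.atc_name] = DrugRecord(
                atc_name=r.atc_name, cids=set(r.cids),
                atc_codes=set(r.atc_codes), interactions=list(r.interactions))
        else:
            tgt.cids |= r.cids
            tgt.atc_codes |= r.atc_codes
            tgt.interactions.extend(r.interactions)
    for r in merged.values():
        seen: set[Interaction] = set()
        dedup = []
        for it in r.interactions:
            if it not in seen:
                seen.add(it)
                dedup.append(it)
        r.interactions = sorted(dedup, key=lambda i: (i.gene_id, i.action, i.source_set))
    return [merged[k] for k in sorted(merged)]


def attach_interactions(records: list[DrugRecord],
                        interactions: pd.DataFrame) -> list[DrugRecord]:
    """Attach typed interactions (drug_name, gene_id, action, source) to the
    matching records by canonical name."""
    by_name = {r.atc_name: r for r in records}
    n_orphan = 0
    for row in interactions.itertuples():
        rec = by_name.get(canonical_name(str(row.drug_name)))
        if rec is None:
            n_orphan += 1
            continue
        rec.interactions.append(Interaction(gene_id=str(row.gene_id),
                                            action=str(row.action),
                                            source_set=str(row.source)))
    if n_orphan:
        log.warning("attach_interactions: %d interaction row(s) for unknown drugs",
                    n_orphan)
    return records


def build_gene_sets(records: list[DrugRecord], tier: str = "annotation",
                    universe: set[str] | None = None) -> list[GeneSet]:
    """One gene-set per drug for the requested evidence tier.

    The annotation tier uses all interactions; the bioactivity tier only
    those with curated binding evidence (so bioactivity sets are subsets of
    the drug's annotation set). Genes outside ``universe`` are dropped.
    Distinct drugs with identical gene-sets keep distinct set_ids; the
    number of distinct gene-sets is logged (it explains sets < drugs).
    """
    if tier not in ("annotation", "bioactivity"):
        raise ValueError(f"unknown tier {tier!r}")
    sets = []
    for r in records:
        its = r.interactions if tier == "annotation" else [
            i for i in r.interactions if i.source_set == "bioactivity"]
        genes = {i.gene_id for i in its}
        if universe is not None:
            genes &= universe
        if genes:
            sets.append(GeneSet(set_id=f"{r.atc_name}|{tier}",
                                gene_ids=frozenset(genes)))
    n_distinct = len({s.gene_ids for s in sets})
    log.info("build_gene_sets(%s): %d drugs -> %d sets, %d distinct gene-sets",
             tier, len(records), len(sets), n_distinct)
    return sets


def annotate_tiers(gene_ids: list[str], tiers: dict[str, str]) -> tuple[list[tuple[str, str]], Counter]:
    """Label each gene T1/T2/T3/none and summarize counts per tier."""
    labeled = []
    for g in gene_ids:
        t = tiers.get(g, "none")
        if t not in DruggabilityTier.VALID:
            raise FormatError(f"invalid tier {t!r} for gene {g}")
        labeled.append((g, t))
    return labeled, Counter(t for _, t in labeled)


def write_gmt(sets: list[GeneSet], path) -> None:
    """GMT-style output: set_id, description, tab-separated gene ids."""
    with open(path, "w") as fh:
        for s in sorted(sets, key=lambda s: s.set_id):
            fh.write("\t".join([s.set_id, "drug gene-set"] + sorted(s.gene_ids)) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(set_id=parts[0], gene_ids=frozenset(parts[2:])))
    return sets
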