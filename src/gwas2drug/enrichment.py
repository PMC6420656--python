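"""Drug gene-set scoring and ATC therapeutic-class enrichment.

Each drug's gene-set is scored against the phenotype by a competitive
regression: gene-level association Z is regressed on a set-membership
indicator plus gene-size covariates, and the one-sided upper-tail p of the
indicator coefficient is the drug's pathway p. Drugs are then ranked in
-log10(p) units and every ATC class (each hierarchical level, pooled) is
tested by a one-sided Mann-Whitney-Wilcoxon rank test — alternative: class
members sit to the right (more associated) — summarized by AUC =
U/(n_in * n_out), with Bonferroni over the number of tested classes and
Benjamini-Hochberg q-values side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, log10

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .drugsets import DrugRecord, GeneSet
from .gene_assoc import GeneResult

log = logging.getLogger(__name__)

COVARIATE_COLS = ["n_snps", "log_n_snps", "length_bp", "log_length_bp"]

ATC_LEVEL_CHARS = {1: 1, 2: 3, 3: 4, 4: 5}

EXACT_MWW_MAX_N = 12  # enumeration bound: C(12, 6) = 924 placements


@dataclass
class PathwayResult:
    """Competitive association of one drug gene-set with the phenotype."""

    set_id: str
    beta_s: float
    p_drug: float
    n_genes_in_set: int


@dataclass
class ClassEnrichment:
    """Rank enrichment of one ATC class among phenotype-ranked drugs."""

    atc_code: str
    level: int
    n_in: int
    n_out: int
    U: float
    auc: float
    p_mww: float
    bonferroni_sig: bool = False
    q_value: float = 1.0


def gene_covariates(results: list[GeneResult]) -> pd.DataFrame:
    """Per-gene covariates for the competitive model: SNP count and gene
    length on natural and log scales."""
    df = pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "n_snps": [float(r.n_snps) for r in results],
        "length_bp": [float(r.length_bp) for r in results],
    }).set_index("gene_id")
    df["log_n_snps"] = np.log(df["n_snps"])
    df["log_length_bp"] = np.log(np.maximum(df["length_bp"], 1.0))
    return df[COVARIATE_COLS]


def competitive_test(gene_z: dict[str, float], gene_set: GeneSet,
                     covariates: pd.DataFrame) -> PathwayResult | None:
    """OLS of gene Z on intercept + set indicator + covariates; the drug p
    is the one-sided upper-tail t-test on the indicator coefficient.

    Genes outside the tested universe (keys of ``gene_z``) are ignored;
    the set must retain at least 2 genes or it is skipped. Collinear
    covariates are dropped with a warning; a degenerate fit (no residual
    variance) reports p = 1.
    """
    genes = sorted(gene_z)
    members = gene_set.gene_ids & set(genes)
    if len(members) < 2:
        log.info("competitive_test: %s retains %d gene(s) in universe; skipped",
                 gene_set.set_id, len(members))
        return None
    y = np.array([gene_z[g] for g in genes])
    if np.ptp(y) == 0:  # no variation in gene association: nothing to explain
        return PathwayResult(set_id=gene_set.set_id, beta_s=0.0, p_drug=1.0,
                             n_genes_in_set=len(members))
    ind = np.array([1.0 if g in members else 0.0 for g in genes])
    cov = covariates.reindex(genes)
    cols = []
    X = np.column_stack([np.ones(len(genes)), ind])
    for c in COVARIATE_COLS:
        if c not in cov.columns:
            continue
        cand = np.column_stack([X, cov[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X = cand
            cols.append(c)
        else:
            log.warning("competitive_test: dropping collinear covariate %s", c)
    n, p_dim = X.shape
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = n - rank
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    if s2 <= 0:
        return PathwayResult(set_id=gene_set.set_id, beta_s=float(beta[1]),
                             p_drug=1.0, n_genes_in_set=len(members))
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(s2 * XtX_inv[1, 1]))
    t = beta[1] / se if se > 0 else 0.0
    p = float(stats.t.sf(t, dof)) if se > 0 else 1.0
    return PathwayResult(set_id=gene_set.set_id, beta_s=float(beta[1]),
                         p_drug=max(min(p, 1.0), 1e-300), n_genes_in_set=len(members))


def run_pathway_analysis(gene_results: list[GeneResult], sets: list[GeneSet],
                         exclude_mhc_genes: bool = True) -> list[PathwayResult]:
    """Score every drug gene-set; MHC genes are excluded from the tested
    universe by default (their extreme LD inflates competitive fits)."""
    use = [r for r in gene_results if not (exclude_mhc_genes and r.in_mhc)]
    gene_z = {r.gene_id: r.z_gene for r in use}
    cov = gene_covariates(use)
    # drop constant / mutually collinear covariates once, not per set
    base = np.ones((len(cov), 1))
    keep = []
    for c in COVARIATE_COLS:
        cand = np.column_stack([base] + [cov[k].to_numpy() for k in keep + [c]])
        if np.linalg.matrix_rank(cand) == len(keep) + 2:
            keep.append(c)
        else:
            log.warning("run_pathway_analysis: dropping collinear covariate %s", c)
    cov = cov[keep]
    out = []
    for s in sorted(sets, key=lambda s: s.set_id):
        r = competitive_test(gene_z, s, cov)
        if r is not None:
            out.append(r)
    return out


def rank_drugs(pathway: list[PathwayResult]) -> list[tuple[str, float]]:
    """Drugs ordered by descending -log10(p_drug); ties broken by set_id."""
    scored = [(r.set_id, -log10(max(r.p_drug, 1e-300))) for r in pathway]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mww_exact_p(scores: np.ndarray, is_member: np.ndarray) -> tuple[float, float]:
    """Exact one-sided MWW by enumerating every placement of the member
    labels over the observed scores (handles ties through midranks).

    Returns (U, exact p). Enumeration cost is C(n, n_in); intended for
    n <= 12 where that is at most 924.
    """
    scores = np.asarray(scores, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    n = len(scores)
    n_in = int(is_member.sum())
    n_out = n - n_in
    ranks = _midranks(scores)
    u_obs = float(ranks[is_member].sum() - n_in * (n_in + 1) / 2)
    count = 0
    total = comb(n, n_in)
    for subset in combinations(range(n), n_in):
        u = float(ranks[list(subset)].sum() - n_in * (n_in + 1) / 2)
        if u >= u_obs - 1e-9:
            count += 1
    return u_obs, count / total


def mww_class_test(ranked: list[tuple[str, float]], class_members: set[str],
                   atc_code: str = "", level: int = 0,
                   exact_max_n: int = EXACT_MWW_MAX_N) -> ClassEnrichment | None:
    """One-sided MWW of class members' scores against the rest.

    Scores are the -log10(p_drug) ranking units; the alternative is that
    members are shifted toward larger scores. Midranks handle ties; the
    normal approximation carries tie and continuity corrections, and exact
    enumeration replaces it when n_in + n_out <= ``exact_max_n``.
    """
    names = [n for n, _ in ranked]
    scores = np.array([s for _, s in ranked])
    mask = np.array([n in class_members for n in names])
    n_in = int(mask.sum())
    n_out = len(names) - n_in
    if n_in == 0 or n_out == 0:
        return None
    if len(names) <= exact_max_n:
        u, p = mww_exact_p(scores, mask)
    else:
        u, p = stats.mannwhitneyu(scores[mask], scores[~mask],
                                  alternative="greater", method="asymptotic")
        u, p = float(u), float(p)
    return ClassEnrichment(atc_code=atc_code, level=level, n_in=n_in,
                           n_out=n_out, U=u, auc=u / (n_in * n_out),
                           p_mww=min(p, 1.0))


def class_memberships(records: list[DrugRecord], levels=(1, 2, 3, 4)) -> dict[tuple[int, str], set[str]]:
    """(level, class prefix) -> member drug names, by code truncation.

    A drug belongs to a class if any of its ATC codes starts with the class
    prefix; drugs without codes belong to no class.
    """
    out: dict[tuple[int, str], set[str]] = {}
    for r in records:
        for code in r.atc_codes:
            for lvl in levels:
                w = ATC_LEVEL_CHARS[lvl]
                if len(code) >= w:
                    out.setdefault((lvl, code[:w]), set()).add(r.atc_name)
    return out


def test_all_classes(ranked: list[tuple[str, float]], records: list[DrugRecord],
                     levels=(1, 2, 3, 4), min_class_size: int = 5,
                     alpha: float = 0.05) -> tuple[list[ClassEnrichment], int]:
    """Test every ATC class at every requested level, pooled for multiple
    testing: Bonferroni at alpha / n_classes_tested and BH q-values over the
    pooled p vector. Classes smaller than ``min_class_size`` among ranked
    drugs are skipped and not counted."""
    ranked_names = {n for n, _ in ranked}
    results: list[ClassEnrichment] = []
    for (lvl, code), members in sorted(class_memberships(records, levels).items()):
        present = members & ranked_names
        if len(present) < min_class_size:
            continue
        ce = mww_class_test(ranked, present, atc_code=code, level=lvl)
        if ce is not None:
            results.append(ce)
    n_tested = len(results)
    if n_tested:
        pvec = np.array([r.p_mww for r in results])
        q = bh_fdr(pvec)
        for r, qi in zip(results, q):
            r.q_value = float(qi)
            r.bonferroni_sig = r.p_mww <= alpha / n_tested
    return results, n_tested


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
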