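"""Summary-statistic imputation of gene-expression association.

Given a per-tissue linear expression-prediction model (sparse SNP weights
plus reference-panel SNP variances and covariances) and GWAS summary
statistics, each gene x tissue pair receives a signed association Z:

    Z_g = sum_l  w_lg * (sigma_l / sigma_g) * (beta_l / se_l)

with sigma_g = sqrt(w' Gamma w) the predicted-expression SD in the reference
panel. The sign of Z is the predicted direction of expression change in
trait cases; multiple-testing control is Bonferroni over all emitted
gene x tissue associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import SnpStat

log = logging.getLogger(__name__)


@dataclass
class ExpressionModel:
    """Per gene x tissue prediction model over a sparse SNP set.

    ``weights`` maps snp_id -> w; ``ref_var`` maps snp_id -> reference
    genotype variance; ``ref_cov`` is the covariance matrix over
    ``snp_order`` (which fixes the row/column order of ``ref_cov``).
    """

    gene_id: str
    tissue: str
    snp_order: list[str]
    weights: dict[str, float]
    ref_var: dict[str, float]
    ref_cov: np.ndarray

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"{self.gene_id}/{self.tissue}: empty weight vector")
        k = len(self.snp_order)
        if self.ref_cov.shape != (k, k):
            raise ValueError("ref_cov shape does not match snp_order")
        if not np.allclose(self.ref_cov, self.ref_cov.T, atol=1e-9):
            raise ValueError("ref_cov not symmetric")
        d = np.diag(self.ref_cov)
        expect = np.array([self.ref_var[s] for s in self.snp_order])
        if not np.allclose(d, expect, rtol=1e-6, atol=1e-9):
            raise ValueError("diag(ref_cov) != ref_var")


@dataclass
class TwasResult:
    """Imputed expression association for one gene x tissue."""

    gene_id: str
    tissue: str
    z: float
    p: float = field(init=False)
    sigma_g: float = 0.0
    direction: str = field(init=False)
    family: str = ""
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        self.p = two_sided_p(self.z)
        self.direction = "+" if self.z >= 0 else "-"


def two_sided_p(z: float) -> float:
    """Two-sided normal p with an accurate complementary tail.

    Uses the survival function directly; a naive 1 - CDF subtraction loses
    all precision past |z| ~ 8.
    """
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def spredixcan_z(model: ExpressionModel, snps: dict[str, SnpStat],
                 family: str = "") -> TwasResult | None:
    """Impute the expression-association Z for one model.

    Model SNPs missing from the summary statistics are dropped (with a
    logged count) and sigma_g is recomputed on the retained subset. Returns
    None when no SNP remains or the retained model is degenerate
    (sigma_g = 0).
    """
    keep = [s for s in model.snp_order if s in snps]
    n_miss = len(model.snp_order) - len(keep)
    if n_miss:
        log.info("%s/%s: %d model SNP(s) missing from summary stats",
                 model.gene_id, model.tissue, n_miss)
    if not keep:
        log.warning("%s/%s: no model SNP present; gene skipped",
                    model.gene_id, model.tissue)
        return None
    idx = [model.snp_order.index(s) for s in keep]
    w = np.array([model.weights[s] for s in keep])
    gamma = model.ref_cov[np.ix_(idx, idx)]
    var_g = float(w @ gamma @ w)
    if var_g <= 0 or np.allclose(w, 0):
        log.warning("%s/%s: degenerate model (sigma_g = 0); skipped",
                    model.gene_id, model.tissue)
        return None
    sigma_g = float(np.sqrt(var_g))
    sigma_l = np.sqrt([model.ref_var[s] for s in keep])
    snp_z = np.array([snps[s].beta / snps[s].se for s in keep])
    z = float(np.sum(w * (sigma_l / sigma_g) * snp_z))
    return TwasResult(gene_id=model.gene_id, tissue=model.tissue, z=z,
                      sigma_g=sigma_g, family=family, n_snps_used=len(keep))


def run_twas(models: list[ExpressionModel], snps: list[SnpStat],
             families: dict[str, str] | None = None) -> list[TwasResult]:
    """Impute association for every model; ``families`` maps tissue -> family."""
    families = families or {}
    by_id = {s.snp_id: s for s in snps}
    out = []
    for m in models:
        r = spredixcan_z(m, by_id, family=families.get(m.tissue, ""))
        if r is not None:
            out.append(r)
    return out


def write_expression_models(models: list[ExpressionModel], weights_path, cov_path) -> None:
    """Serialize models as a weight TSV (gene_id, tissue, snp, weight) and a
    covariance TSV (gene_id, tissue, snp_i, snp_j, cov; upper triangle)."""
    import pandas as pd

    wrows, crows = [], []
    for m in models:
        for s in m.snp_order:
            wrows.append((m.gene_id, m.tissue, s, m.weights[s]))
        for i, si in enumerate(m.snp_order):
            for j in range(i, len(m.snp_order)):
                crows.append((m.gene_id, m.tissue, si, m.snp_order[j],
                              float(m.ref_cov[i, j])))
    pd.DataFrame(wrows, columns=["gene_id", "tissue", "snp", "weight"]).to_csv(
        weights_path, sep="\t", index=False)
    pd.DataFrame(crows, columns=["gene_id", "tissue", "snp_i", "snp_j", "cov"]).to_csv(
        cov_path, sep="\t", index=False)


def read_expression_models(weights_path, cov_path) -> list[ExpressionModel]:
    """Inverse of :func:`write_expression_models`."""
    import pandas as pd

    wdf = pd.read_csv(weights_path, sep="\t")
    cdf = pd.read_csv(cov_path, sep="\t")
    models = []
    cov_groups = {k: g for k, g in cdf.groupby(["gene_id", "tissue"], sort=False)}
    for (gene, tissue), g in wdf.groupby(["gene_id", "tissue"], sort=False):
        order = list(g["snp"])
        weights = dict(zip(g["snp"], g["weight"].astype(float)))
        k = len(order)
        pos = {s: i for i, s in enumerate(order)}
        cov = np.zeros((k, k))
        for r in cov_groups[(gene, tissue)].itertuples():
            i, j = pos[r.snp_i], pos[r.snp_j]
            cov[i, j] = cov[j, i] = r.cov
        ref_var = {s: float(cov[pos[s], pos[s]]) for s in order}
        models.append(ExpressionModel(gene_id=gene, tissue=tissue, snp_order=order,
                                      weights=weights, ref_var=ref_var, ref_cov=cov))
    return models


def transcriptome_threshold(alpha: float, n_assoc: int) -> float:
    """Bonferroni threshold over all emitted gene x tissue associations."""
    if n_assoc < 1:
        raise ValueError("n_assoc must be >= 1")
    return alpha / n_assoc


def direction_table(results: list[TwasResult], genes: list[str],
                    families: dict[str, str],
                    threshold: float | None = None) -> dict[str, dict[str, dict]]:
    """Per gene and tissue family, the multiset of +/- direction calls.

    Returns gene_id -> family -> {"calls": "+, -", "significant": bool},
    where ``significant`` flags any call passing ``threshold``. Genes with
    no model in a family get an empty cell.
    """
    fam_names = sorted(set(families.values()))
    table: dict[str, dict[str, dict]] = {
        g: {f: {"calls": "", "significant": False} for f in fam_names} for g in genes
    }
    for r in sorted(results, key=lambda r: (r.gene_id, r.tissue)):
        fam = families.get(r.tissue)
        if fam is None or r.gene_id not in table:
            continue
        cell = table[r.gene_id][fam]
        cell["calls"] = (cell["calls"] + ", " if cell["calls"] else "") + r.direction
        if threshold is not None and r.p <= threshold:
            cell["significant"] = True
    return table
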