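"""Gene-based association from SNP summary statistics, accounting for LD.

SNPs are mapped to genes through strand-aware windows (default 35 kb
upstream, 10 kb downstream of the gene body). Two gene statistics are
computed from the mapped z-scores and the LD reference:

* mean model — t = sum z_i^2, whose null under MVN(0, R) is the eigenvalue
  mixture sum lambda_j chi2_1. The tail is evaluated by a saddlepoint
  approximation (exact scaled chi-square when all eigenvalues coincide),
  with the Satterthwaite moment match c * chi2_f, c = tr(R^2)/k,
  f = k^2/tr(R^2), as the degenerate-saddlepoint fallback.
* top model — the minimum two-sided SNP p, calibrated against seeded
  multivariate-normal null simulation.

The two are aggregated by a correlation-adjusted Stouffer combination
("multi"), with the probit-null correlation estimated from the same null
draws. Genes overlapping the MHC (chr6:25-35 Mb) are flagged, and the
genome-wide threshold is Bonferroni over the number of tested genes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .io_formats import GeneAnnotation, LDReference, SnpStat

log = logging.getLogger(__name__)

MHC_CHROM = "6"
MHC_LO = 25_000_000
MHC_HI = 35_000_000

P_FLOOR = 1e-300  # clamp before probit so z_gene stays finite


@dataclass
class GeneResult:
    """Per-gene association summary."""

    gene_id: str
    n_snps: int
    t_mean: float
    p_mean: float
    p_top: float
    p_multi: float
    z_gene: float = field(init=False)
    in_mhc: bool = False
    tier: str = "none"
    length_bp: int = 0

    def __post_init__(self) -> None:
        pm = min(max(self.p_multi, P_FLOOR), 1.0)
        self.z_gene = float(stats.norm.isf(pm))


def map_snps_to_genes(snps: list[SnpStat], genes: list[GeneAnnotation],
                      up_kb: float = 35.0, down_kb: float = 10.0,
                      ignore_strand: bool = False) -> dict[str, list[SnpStat]]:
    """Window mapping: SNP -> gene iff inside [start-up, end+down] on the
    plus strand or [start-down, end+up] on the minus strand (bp, inclusive).

    With ``ignore_strand`` the plus-strand convention applies to all genes.
    A SNP may map to several genes.
    """
    snp_chroms = {s.chrom for s in snps}
    gene_chroms = {g.chrom for g in genes}
    if snps and genes and not (snp_chroms & gene_chroms):
        raise ValueError(
            f"no chromosome in common between GWAS ({sorted(snp_chroms)[:5]}) "
            f"and annotation ({sorted(gene_chroms)[:5]})")
    up, down = int(up_kb * 1000), int(down_kb * 1000)
    by_chrom: dict[str, list[SnpStat]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    mapping: dict[str, list[SnpStat]] = {}
    for g in genes:
        if g.strand == "+" or ignore_strand:
            lo, hi = g.start - up, g.end + down
        else:
            lo, hi = g.start - down, g.end + up
        chrom_snps = by_chrom.get(g.chrom, [])
        pos = [s.pos for s in chrom_snps]
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        hit = chrom_snps[i:j]
        if hit:
            mapping[g.gene_id] = hit
    return mapping


def satterthwaite_p(t: float | np.ndarray, R: np.ndarray) -> float | np.ndarray:
    """Scaled-chi2 moment match to the eigenvalue mixture sum lambda_j chi2_1:
    c = tr(R^2)/k, f = k^2/tr(R^2). Exact when all eigenvalues are equal."""
    k = R.shape[0]
    tr2 = float(np.sum(R * R))  # trace(R @ R) for symmetric R
    return stats.chi2.sf(np.asarray(t) / (tr2 / k), k * k / tr2)


def _saddlepoint_tail(t: float, lam: np.ndarray) -> float:
    """Lugannani-Rice saddlepoint tail of sum lambda_j chi2_1 at t."""
    from scipy.optimize import brentq

    mean = lam.sum()
    kprime = lambda z: np.sum(lam / (1.0 - 2.0 * z * lam))
    hi = 1.0 / (2.0 * lam.max()) - 1e-10
    lo = -1.0
    while kprime(lo) > t:
        lo *= 2.0
        if lo < -1e12:
            return float("nan")
    zhat = brentq(lambda z: kprime(z) - t, lo, hi, xtol=1e-14)
    K = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    K2 = np.sum(2.0 * lam ** 2 / (1.0 - 2.0 * zhat * lam) ** 2)
    arg = 2.0 * (zhat * t - K)
    if arg <= 0:
        return float("nan")
    w = np.sign(zhat) * np.sqrt(arg)
    v = zhat * np.sqrt(K2)
    if abs(w) < 1e-6 or v == 0:
        return float("nan")  # t at the distribution mean; caller falls back
    return float(stats.norm.sf(w + np.log(v / w) / w))


_ruben_cache: dict[bytes, tuple | None] = {}

_RUBEN_MAX_TERMS = 6000


def _ruben_coefficients(lam: np.ndarray) -> tuple | None:
    """Chi-square series weights for the mixture sum lambda_j chi2_1.

    With beta = min(lambda), P(Q > t) = sum_j a_j P(chi2_{k+2j} > t/beta)
    where the non-negative a_j sum to 1; the truncated tail mass bounds the
    series error. Returns (a, tail_mass, beta, dofs), or None when the
    eigenvalue spread would need more than _RUBEN_MAX_TERMS terms.
    """
    key = lam.tobytes()
    if key in _ruben_cache:
        return _ruben_cache[key]
    beta = float(lam.min())
    v = 1.0 - beta / lam
    q = float(v.max())
    n_terms = (int(np.ceil(np.log(1e-16) / np.log(q))) + 60) if q > 0 else 60
    out = None
    if n_terms <= _RUBEN_MAX_TERMS:
        a0 = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
        if a0 > 0:
            d = 0.5 * np.array([np.sum(v ** r) for r in range(1, n_terms + 1)])
            c = np.empty(n_terms + 1)
            c[0] = 1.0
            for j in range(1, n_terms + 1):
                c[j] = np.dot(d[:j][::-1], c[:j]) / j
            a = a0 * c
            tail_mass = 1.0 - np.cumsum(a)
            dofs = len(lam) + 2.0 * np.arange(n_terms + 1)
            out = (a, tail_mass, beta, dofs)
    if len(_ruben_cache) > 1024:
        _ruben_cache.clear()
    _ruben_cache[key] = out
    return out


def _ruben_tail(t: float, lam: np.ndarray) -> float:
    """Series evaluation of the mixture upper tail; NaN when the series
    cannot reach ~1e-6 relative accuracy (caller falls back)."""
    coeffs = _ruben_coefficients(lam)
    if coeffs is None:
        return float("nan")
    a, tail_mass, beta, dofs = coeffs
    sf = stats.chi2.sf(t / beta, dofs)
    partial = np.cumsum(a * sf)
    ok = tail_mass < np.maximum(1e-12, 1e-6 * partial)
    if ok.any():
        return float(partial[int(np.argmax(ok))])
    if tail_mass[-1] < 0.01 * partial[-1]:
        return float(partial[-1])
    return float("nan")


def mixture_tail_p(t: float, R: np.ndarray) -> float:
    """Upper tail of the quadratic-form null sum lambda_j chi2_1 at t.

    Equal eigenvalues reduce exactly to a scaled chi-square; otherwise the
    tail is a chi-square series evaluation with a controlled truncation
    bound, falling back to the saddlepoint approximation for eigenvalue
    spreads where the series converges too slowly and to the Satterthwaite
    moment match when the saddlepoint is degenerate (t at the null mean).
    """
    lam = np.linalg.eigvalsh(R)
    lam = lam[lam > 1e-10]
    if len(lam) == 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-9):
        return float(stats.chi2.sf(t / lam[0], len(lam)))
    p = _ruben_tail(t, lam)
    if not np.isfinite(p):
        p = _saddlepoint_tail(t, lam)
    if not np.isfinite(p):
        p = float(satterthwaite_p(t, R))
    return min(max(p, 0.0), 1.0)


def gene_test_mean(z: np.ndarray, R: np.ndarray) -> tuple[float, float]:
    """Sum-of-squares statistic and its eigenvalue-mixture tail p-value."""
    z = np.asarray(z, dtype=float)
    k = len(z)
    if R.shape != (k, k):
        raise ValueError("z and R dimension mismatch")
    t = float(np.sum(z ** 2))
    p = mixture_tail_p(t, R)
    return t, max(p, P_FLOOR)


_null_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _null_draws(R: np.ndarray, n_sims: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded null samples of (min two-sided p, sum z^2) under MVN(0, R).

    Genes sharing a byte-identical R reuse one simulation; the stream seed
    mixes the user seed with a hash of R so results are reproducible yet
    distinct across LD structures.
    """
    digest = hashlib.blake2b(R.tobytes() + R.shape[0].to_bytes(4, "little"),
                             digest_size=8).digest()
    key = (digest, n_sims, seed)
    hit = _null_cache.get(key)
    if hit is not None:
        return hit
    sub = int.from_bytes(digest[:4], "little")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(sub,)))
    k = R.shape[0]
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    Z = rng.standard_normal((n_sims, k)) @ L.T
    min_p = 2.0 * stats.norm.sf(np.abs(Z).max(axis=1))
    t_mean = np.sum(Z ** 2, axis=1)
    if len(_null_cache) > 4096:
        _null_cache.clear()
    _null_cache[key] = (min_p, t_mean)
    return min_p, t_mean


def gene_test_top(z: np.ndarray, R: np.ndarray, n_sims: int = 10_000,
                  seed: int = 0) -> float:
    """Empirical p of the minimum two-sided SNP p under the MVN null."""
    z = np.asarray(z, dtype=float)
    obs = float(2.0 * stats.norm.sf(np.abs(z).max()))
    null_min_p, _ = _null_draws(R, n_sims, seed)
    return float((1 + np.sum(null_min_p <= obs)) / (n_sims + 1))


_rho_cache: dict[tuple, float] = {}


def estimate_rho_mt(R: np.ndarray, n_sims: int = 10_000, seed: int = 0) -> float:
    """Correlation of the probit-transformed mean and top null statistics.

    Both null samples come from the same draws used by the top test; each is
    converted to a null p (scaled-chi2 moment match for the mean — a
    monotone transform, which is all the probit correlation needs — and
    empirical rank for the top) and probit-transformed before taking the
    Pearson correlation. Cached per (R, n_sims, seed) like the null draws.
    """
    digest = hashlib.blake2b(R.tobytes() + R.shape[0].to_bytes(4, "little"),
                             digest_size=8).digest()
    key = (digest, n_sims, seed)
    hit = _rho_cache.get(key)
    if hit is not None:
        return hit
    null_min_p, null_t = _null_draws(R, n_sims, seed)
    p_mean = satterthwaite_p(null_t, R)
    ranks = stats.rankdata(null_min_p, method="average")
    p_top = ranks / (len(ranks) + 1)
    zm = stats.norm.isf(np.clip(p_mean, P_FLOOR, 1 - 1e-16))
    zt = stats.norm.isf(np.clip(p_top, P_FLOOR, 1 - 1e-16))
    rho = float(np.corrcoef(zm, zt)[0, 1])
    rho = min(max(rho, -1.0), 1.0)
    if len(_rho_cache) > 4096:
        _rho_cache.clear()
    _rho_cache[key] = rho
    return rho


def combine_multi(p_mean: float, p_top: float, rho_mt: float) -> float:
    """Correlation-adjusted Stouffer aggregation of the two gene models."""
    if not -1.0 <= rho_mt <= 1.0:
        raise ValueError(f"rho_mt outside [-1, 1]: {rho_mt}")
    zm = stats.norm.isf(min(max(p_mean, P_FLOOR), 1 - 1e-16))
    zt = stats.norm.isf(min(max(p_top, P_FLOOR), 1 - 1e-16))
    denom = np.sqrt(2.0 + 2.0 * rho_mt) if rho_mt > -1.0 else np.inf
    if not np.isfinite(denom) or denom == 0:
        return 0.5
    p = float(stats.norm.sf((zm + zt) / denom))
    return min(max(p, P_FLOOR), 1.0)


def in_mhc(gene: GeneAnnotation, chrom: str = MHC_CHROM,
           lo_bp: int = MHC_LO, hi_bp: int = MHC_HI) -> bool:
    """True iff the gene body (before windows) overlaps the closed region."""
    return gene.chrom == chrom and gene.start <= hi_bp and gene.end >= lo_bp


def exclude_mhc(results: list[GeneResult], genes: list[GeneAnnotation],
                chrom: str = MHC_CHROM, lo_bp: int = MHC_LO,
                hi_bp: int = MHC_HI) -> list[GeneResult]:
    """Set the in_mhc flag on each result from its gene span."""
    by_id = {g.gene_id: g for g in genes}
    for r in results:
        g = by_id.get(r.gene_id)
        if g is not None:
            r.in_mhc = in_mhc(g, chrom, lo_bp, hi_bp)
    return results


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests, reported at 3 significant figures."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(f"{alpha / n_tests:.3g}")


def run_gene_assoc(snps: list[SnpStat], genes: list[GeneAnnotation],
                   ld: LDReference, tiers: dict[str, str] | None = None,
                   up_kb: float = 35.0, down_kb: float = 10.0,
                   n_sims: int = 10_000, seed: int = 0,
                   ignore_strand: bool = False) -> list[GeneResult]:
    """Full gene-based analysis: window mapping, mean/top/multi tests,
    MHC flags and druggability tiers.

    SNPs absent from the LD reference are dropped from a gene's test with a
    logged count; genes retaining no SNP are not reported. A gene whose SNPs
    span several LD blocks uses the block-diagonal correlation (cross-block
    LD is zero by the reference's construction).
    """
    tiers = tiers or {}
    mapping = map_snps_to_genes(snps, genes, up_kb, down_kb, ignore_strand)
    snp_loc = ld.snp_index()
    by_id = {g.gene_id: g for g in genes}
    results: list[GeneResult] = []
    n_dropped = 0
    for gene_id in sorted(mapping):
        gsnps = mapping[gene_id]
        known = [s for s in gsnps if s.snp_id in snp_loc]
        n_dropped += len(gsnps) - len(known)
        if not known:
            continue
        # deterministic order: block, then position within block
        known.sort(key=lambda s: snp_loc[s.snp_id])
        z = np.array([s.z for s in known])
        blocks: dict[int, list[int]] = {}
        for s in known:
            b, j = snp_loc[s.snp_id]
            blocks.setdefault(b, []).append(j)
        subs = [ld.blocks[b][1][np.ix_(idx, idx)] for b, idx in sorted(blocks.items())]
        R = subs[0] if len(subs) == 1 else linalg.block_diag(*subs)
        t_mean, p_mean = gene_test_mean(z, R)
        p_top = gene_test_top(z, R, n_sims=n_sims, seed=seed)
        rho = estimate_rho_mt(R, n_sims=n_sims, seed=seed)
        p_multi = combine_multi(p_mean, p_top, rho)
        g = by_id[gene_id]
        results.append(GeneResult(
            gene_id=gene_id, n_snps=len(known), t_mean=t_mean,
            p_mean=p_mean, p_top=p_top, p_multi=p_multi,
            tier=tiers.get(gene_id, "none"), length_bp=g.length_bp,
        ))
    if n_dropped:
        log.warning("run_gene_assoc: dropped %d mapped SNP(s) absent from LD reference",
                    n_dropped)
    exclude_mhc(results, genes)
    return results
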