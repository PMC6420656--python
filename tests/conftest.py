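import logging

import numpy as np
import pytest

from gwas2drug.io_formats import GeneAnnotation, LDReference, SnpStat
from gwas2drug.synth import SimulationConfig, simulate_study


@pytest.fixture(autouse=True)
def _quiet_logging():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture(scope="session")
def small_study():
    """One small planted study shared by read-only tests."""
    cfg = SimulationConfig(seed=42, n_genes=120, n_causal_genes=12,
                           n_drugs=60, n_atc_classes=8, planted_class_size=12)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_snp(snp_id="rs1", chrom="1", pos=100, a1="A", a2="G",
             beta=0.1, se=0.05, p=0.5, n=1000):
    return SnpStat(snp_id=snp_id, chrom=chrom, pos=pos, a1=a1, a2=a2,
                   beta=beta, se=se, p=p, n=n)


def make_gene(gene_id="G1", chrom="1", start=100_000, end=110_000, strand="+"):
    return GeneAnnotation(gene_id=gene_id, symbol=gene_id, chrom=chrom,
                          start=start, end=end, strand=strand)


def random_correlation(k: int, rng) -> np.ndarray:
    """A random full-rank correlation matrix."""
    from scipy.stats import random_correlation as rc
    ev = rng.uniform(0.2, 2.0, size=k)
    ev = ev * k / ev.sum()
    return rc.rvs(ev, random_state=np.random.default_rng(rng.integers(2**31)))


@pytest.fixture
def ld_identity():
    ids = [f"s{i}" for i in range(4)]
    return LDReference(blocks=[(ids, np.eye(4))])
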