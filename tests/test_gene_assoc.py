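"""Gene-based association: window mapping, mean/top/multi models, MHC flag
and Bonferroni arithmetic, each against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwas2drug import gene_assoc as ga
from gwas2drug.io_formats import LDReference
from gwas2drug.synth import ar1_correlation

from conftest import make_gene, make_snp, random_correlation


class TestWindowMapping:
    def test_plus_strand_closed_upstream_boundary(self):
        gene = make_gene(start=100_000, end=110_000, strand="+")
        inside = make_snp(snp_id="in", pos=65_000)    # 100000 - 35000
        outside = make_snp(snp_id="out", pos=64_999)
        m = ga.map_snps_to_genes([inside, outside], [gene])
        assert [s.snp_id for s in m["G1"]] == ["in"]

    def test_minus_strand_flips_window(self):
        gene = make_gene(start=100_000, end=110_000, strand="-")
        m = ga.map_snps_to_genes([make_snp(pos=145_000)], [gene])
        assert "G1" in m  # end + 35 kb on the minus strand
        m2 = ga.map_snps_to_genes([make_snp(pos=145_001)], [gene])
        assert "G1" not in m2

    def test_ignore_strand_uses_plus_convention(self):
        gene = make_gene(start=100_000, end=110_000, strand="-")
        m = ga.map_snps_to_genes([make_snp(pos=65_000)], [gene], ignore_strand=True)
        assert "G1" in m

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            ga.map_snps_to_genes([make_snp(chrom="chr1")],
                                 [make_gene(chrom="1")])

    def test_snp_may_map_to_several_genes(self):
        g1 = make_gene(gene_id="A", start=100_000, end=110_000)
        g2 = make_gene(gene_id="B", start=105_000, end=115_000)
        m = ga.map_snps_to_genes([make_snp(pos=107_000)], [g1, g2])
        assert set(m) == {"A", "B"}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_interval_oracle(self, data):
        n_genes = data.draw(st.integers(1, 6))
        genes = []
        for i in range(n_genes):
            start = data.draw(st.integers(50_000, 500_000))
            length = data.draw(st.integers(1, 50_000))
            strand = data.draw(st.sampled_from("+-"))
            genes.append(make_gene(gene_id=f"G{i}", start=start,
                                   end=start + length, strand=strand))
        snps = [make_snp(snp_id=f"rs{j}", pos=data.draw(st.integers(1, 600_000)))
                for j in range(data.draw(st.integers(1, 15)))]
        got = ga.map_snps_to_genes(snps, genes, up_kb=35, down_kb=10)
        for g in genes:
            lo = g.start - (35_000 if g.strand == "+" else 10_000)
            hi = g.end + (10_000 if g.strand == "+" else 35_000)
            expect = sorted(s.snp_id for s in snps if lo <= s.pos <= hi)
            assert sorted(s.snp_id for s in got.get(g.gene_id, [])) == expect


class TestMeanModel:
    def test_single_snp_reduces_to_two_sided_p(self):
        t, p = ga.gene_test_mean(np.array([2.0]), np.eye(1))
        assert t == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
        assert p == pytest.approx(0.0455, abs=3e-4)

    def test_identity_ld_gives_exact_chi2(self):
        z = np.arange(1, 11) / 4.0
        t, p = ga.gene_test_mean(z, np.eye(10))
        assert p == pytest.approx(stats.chi2.sf(float(np.sum(z ** 2)), 10), rel=1e-9)

    def test_satterthwaite_moment_match_formula(self):
        R = ar1_correlation(6, 0.6)
        k, tr2 = 6, float(np.sum(R * R))
        t = 14.0
        expect = stats.chi2.sf(t / (tr2 / k), k * k / tr2)
        assert ga.satterthwaite_p(t, R) == pytest.approx(expect, rel=1e-12)

    def test_ar1_tail_matches_monte_carlo(self, rng):
        # empirical 99th percentile of the null statistic should get
        # p close to 0.01 from the analytic tail
        R = ar1_correlation(8, 0.8)
        L = np.linalg.cholesky(R)
        draws = rng.standard_normal((200_000, 8)) @ L.T
        t_null = np.sum(draws ** 2, axis=1)
        t_star = float(np.quantile(t_null, 0.99))
        _, p = ga.gene_test_mean(np.sqrt(t_star / 8) * np.ones(8), R)
        assert p == pytest.approx(0.01, rel=0.15)

    def test_monotone_in_signal(self):
        R = ar1_correlation(5, 0.5)
        z = np.array([0.5, -1.0, 1.5, 0.2, -0.3])
        _, p1 = ga.gene_test_mean(z, R)
        _, p2 = ga.gene_test_mean(2 * z, R)
        assert p2 < p1

    def test_mixture_tail_against_random_ld_oracle(self, rng):
        # saddlepoint vs empirical eigen-mixture tail on random small blocks
        for _ in range(5):
            k = int(rng.integers(2, 7))
            R = random_correlation(k, rng)
            lam = np.linalg.eigvalsh(R)
            t_null = (rng.standard_normal((100_000, k)) ** 2 * lam).sum(axis=1)
            t_star = float(np.quantile(t_null, 0.99))
            assert ga.mixture_tail_p(t_star, R) == pytest.approx(0.01, rel=0.2)


class TestTopModel:
    def test_single_snp_recovers_snp_p(self):
        z = np.array([2.5])
        p_top = ga.gene_test_top(z, np.eye(1), n_sims=10_000, seed=3)
        expect = 2 * stats.norm.sf(2.5)
        assert p_top == pytest.approx(expect, abs=2 / np.sqrt(10_000))

    def test_independent_snps_match_sidak(self):
        z = np.array([0.1, 0.2, 2.8, 0.5, 1.0])
        q = 2 * stats.norm.sf(2.8)
        expect = 1 - (1 - q) ** 5
        p_top = ga.gene_test_top(z, np.eye(5), n_sims=20_000, seed=4)
        assert p_top == pytest.approx(expect, abs=3 / np.sqrt(20_000))

    def test_null_z_gives_p_near_one(self):
        p_top = ga.gene_test_top(np.zeros(4), np.eye(4), n_sims=2_000, seed=5)
        assert p_top > 0.99

    def test_deterministic_given_seed(self):
        R = ar1_correlation(4, 0.3)
        z = np.array([1.0, -2.0, 0.5, 0.1])
        assert (ga.gene_test_top(z, R, 2_000, seed=9)
                == ga.gene_test_top(z, R, 2_000, seed=9))


class TestCombineMulti:
    def test_perfect_dependence_returns_p(self):
        assert ga.combine_multi(0.03, 0.03, 1.0) == pytest.approx(0.03, rel=1e-9)

    def test_half_is_fixed_point(self):
        for rho in (0.0, 0.4, 0.9):
            assert ga.combine_multi(0.5, 0.5, rho) == pytest.approx(0.5, rel=1e-9)

    def test_independent_stouffer_arithmetic(self):
        # z_0.05 = 1.6449; p = 1 - Phi(2 * 1.6449 / sqrt(2)) ~ 0.0100
        p = ga.combine_multi(0.05, 0.05, 0.0)
        assert p == pytest.approx(0.010005, abs=1e-5)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ga.combine_multi(0.1, 0.1, 1.5)


class TestMhc:
    def test_partial_overlap_flagged(self):
        assert ga.in_mhc(make_gene(chrom="6", start=24_900_000, end=25_100_000))

    def test_closed_boundary_at_35mb(self):
        assert ga.in_mhc(make_gene(chrom="6", start=35_000_000, end=35_500_000))
        assert not ga.in_mhc(make_gene(chrom="6", start=35_000_001, end=35_500_000))

    def test_other_chromosome_never_flagged(self):
        assert not ga.in_mhc(make_gene(chrom="7", start=25_000_000, end=35_000_000))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(chrom=st.sampled_from(["5", "6", "7"]),
           start=st.integers(1, 50_000_000), length=st.integers(0, 5_000_000))
    def test_matches_interval_overlap_oracle(self, chrom, start, length):
        g = make_gene(chrom=chrom, start=start, end=start + length)
        expect = chrom == "6" and max(start, 25_000_000) <= min(start + length, 35_000_000)
        assert ga.in_mhc(g) == expect


class TestBonferroni:
    def test_genome_wide_threshold(self):
        assert ga.bonferroni_threshold(0.05, 19_079) == pytest.approx(2.62e-6)

    def test_transcriptome_threshold(self):
        assert ga.bonferroni_threshold(0.05, 44_718) == pytest.approx(1.12e-6)

    def test_single_test(self):
        assert ga.bonferroni_threshold(0.05, 1) == 0.05


class TestRunGeneAssoc:
    def test_single_snp_gene_consistency(self):
        snp = make_snp(pos=105_000, beta=0.12, se=0.05, p=2 * stats.norm.sf(2.4))
        gene = make_gene()
        ld = LDReference(blocks=[([snp.snp_id], np.eye(1))])
        [res] = ga.run_gene_assoc([snp], [gene], ld, n_sims=20_000, seed=1)
        expect = 2 * stats.norm.sf(abs(snp.z))
        assert res.p_mean == pytest.approx(expect, rel=1e-6)
        assert res.p_top == pytest.approx(expect, abs=2 / np.sqrt(20_000))
        assert res.p_multi == pytest.approx(expect, rel=0.1)

    def test_snps_missing_from_ld_are_dropped(self):
        snps = [make_snp(snp_id="a", pos=105_000), make_snp(snp_id="b", pos=106_000)]
        ld = LDReference(blocks=[(["a"], np.eye(1))])
        [res] = ga.run_gene_assoc(snps, [make_gene()], ld, n_sims=500, seed=1)
        assert res.n_snps == 1

    def test_z_gene_finite_for_extreme_p(self):
        r = ga.GeneResult("G", 1, 1.0, 1e-320, 1e-320, 0.0)
        assert np.isfinite(r.z_gene)
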