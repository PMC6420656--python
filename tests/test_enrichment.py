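"""Competitive gene-set scoring and ATC-class rank enrichment against
enumeration and pairwise-comparison oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwas2drug import enrichment as en
from gwas2drug.drugsets import DrugRecord, GeneSet
from gwas2drug.gene_assoc import GeneResult


def make_gene_results(z_by_gene, n_snps=10, length=10_000):
    return [GeneResult(gene_id=g, n_snps=n_snps, t_mean=1.0, p_mean=0.5,
                       p_top=0.5, p_multi=float(stats.norm.sf(z)),
                       length_bp=length)
            for g, z in z_by_gene.items()]


class TestCompetitiveTest:
    def test_constant_z_reports_p_one(self):
        gene_z = {f"G{i}": 1.0 for i in range(20)}
        cov = en.gene_covariates(make_gene_results(gene_z))
        r = en.competitive_test(gene_z, GeneSet("s", frozenset(["G1", "G2"])), cov)
        assert r.p_drug == 1.0

    def test_set_smaller_than_two_in_universe_skipped(self):
        gene_z = {"G1": 1.0, "G2": 0.0}
        cov = en.gene_covariates(make_gene_results(gene_z))
        assert en.competitive_test(gene_z, GeneSet("s", frozenset(["G1", "ZZ"])), cov) is None

    def test_elevated_set_detected(self, rng):
        gene_z = {f"G{i}": float(rng.normal()) for i in range(300)}
        members = [f"G{i}" for i in range(20)]
        for m in members:
            gene_z[m] += 3.0
        cov = en.gene_covariates(make_gene_results(gene_z))
        r = en.competitive_test(gene_z, GeneSet("s", frozenset(members)), cov)
        assert r.p_drug < 1e-6
        assert r.beta_s > 0

    def test_matches_statsmodels_ols_oracle(self, rng):
        import statsmodels.api as sm
        genes = [f"G{i}" for i in range(50)]
        gene_z = {g: float(rng.normal()) for g in genes}
        results = make_gene_results(gene_z, n_snps=0, length=0)
        for r, k in zip(results, rng.integers(2, 30, size=50)):
            r.n_snps = int(k)
            r.length_bp = int(k) * 500
        cov = en.gene_covariates(results)
        members = frozenset(rng.choice(genes, size=10, replace=False))
        got = en.competitive_test(gene_z, GeneSet("s", members), cov)
        y = np.array([gene_z[g] for g in sorted(genes)])
        X = np.column_stack([
            np.array([1.0 if g in members else 0.0 for g in sorted(genes)]),
            cov.reindex(sorted(genes)).to_numpy()])
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        t = fit.tvalues[1]
        expect = stats.t.sf(t, fit.df_resid)
        assert got.p_drug == pytest.approx(expect, rel=1e-6)
        assert got.beta_s == pytest.approx(fit.params[1], rel=1e-6)


class TestRankDrugs:
    def test_orders_by_increasing_p(self):
        pr = [en.PathwayResult(s, 0.0, p, 3)
              for s, p in [("a", 0.5), ("b", 0.001), ("c", 0.01)]]
        assert [n for n, _ in en.rank_drugs(pr)] == ["b", "c", "a"]

    def test_ties_break_by_id(self):
        pr = [en.PathwayResult(s, 0.0, 0.05, 3) for s in ("z", "a", "m")]
        assert [n for n, _ in en.rank_drugs(pr)] == ["a", "m", "z"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=10, unique=True))
    def test_order_invariant_under_monotone_transform_of_p(self, ps):
        pr = [en.PathwayResult(f"s{i}", 0.0, p, 3) for i, p in enumerate(ps)]
        pr2 = [en.PathwayResult(f"s{i}", 0.0, p ** 2, 3) for i, p in enumerate(ps)]
        assert [n for n, _ in en.rank_drugs(pr)] == [n for n, _ in en.rank_drugs(pr2)]


class TestMww:
    def test_perfect_separation_auc_one(self):
        ranked = [(f"d{i}", 10.0 - i) for i in range(10)]
        ce = en.mww_class_test(ranked, {f"d{i}" for i in range(3)})
        assert ce.auc == pytest.approx(1.0)

    def test_three_vs_three_perfect_exact_p(self):
        ranked = [(f"d{i}", 6.0 - i) for i in range(6)]
        ce = en.mww_class_test(ranked, {"d0", "d1", "d2"})
        assert ce.p_mww == pytest.approx(1 / comb(6, 3))  # 0.05

    def test_null_symmetry_auc_near_half(self, rng):
        aucs = []
        for _ in range(200):
            scores = rng.normal(size=40)
            ranked = [(f"d{i}", float(s)) for i, s in enumerate(scores)]
            members = {f"d{i}" for i in rng.choice(40, size=10, replace=False)}
            aucs.append(en.mww_class_test(ranked, members).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_reported_p_matches_enumeration_for_small_n(self, rng):
        # tie-free scores, all n_in, n_out <= 6: the class test must report
        # the exact enumeration p at these sizes (n <= EXACT_MWW_MAX_N)
        for n_in in range(1, 7):
            for n_out in range(1, 7):
                n = n_in + n_out
                scores = rng.normal(size=n)
                while len(np.unique(scores)) < n:
                    scores = rng.normal(size=n)
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=n_in, replace=False)] = True
                _, p_exact = en.mww_exact_p(scores, mask)
                ranked = [(f"d{i}", float(s)) for i, s in enumerate(scores)]
                ce = en.mww_class_test(
                    ranked, {f"d{i}" for i in range(n) if mask[i]})
                assert ce.p_mww == pytest.approx(p_exact, abs=1e-12)

    def test_asymptotic_branch_close_to_exact_where_used(self, rng):
        # just past the enumeration bound the normal approximation must
        # already be accurate
        for n_in, n_out in [(6, 7), (7, 7), (5, 10), (8, 8)]:
            n = n_in + n_out
            scores = rng.normal(size=n)
            while len(np.unique(scores)) < n:
                scores = rng.normal(size=n)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_in, replace=False)] = True
            _, p_exact = en.mww_exact_p(scores, mask)
            ranked = [(f"d{i}", float(s)) for i, s in enumerate(scores)]
            ce = en.mww_class_test(
                ranked, {f"d{i}" for i in range(n) if mask[i]}, exact_max_n=0)
            assert abs(ce.p_mww - p_exact) <= 0.02

    def test_auc_equals_pairwise_comparison_fraction(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            n_in = int(rng.integers(1, n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_in, replace=False)] = True
            ranked = [(f"d{i}", float(s)) for i, s in enumerate(scores)]
            ce = en.mww_class_test(ranked, {f"d{i}" for i in range(n) if mask[i]},
                                   exact_max_n=0)
            wins = sum((a > b) + 0.5 * (a == b)
                       for a in scores[mask] for b in scores[~mask])
            assert ce.auc == pytest.approx(wins / (n_in * (n - n_in)), rel=1e-9)

    def test_complementary_auc_sums_to_one(self, rng):
        scores = rng.normal(size=20)
        ranked = [(f"d{i}", float(s)) for i, s in enumerate(scores)]
        members = {f"d{i}" for i in range(8)}
        others = {f"d{i}" for i in range(8, 20)}
        a1 = en.mww_class_test(ranked, members).auc
        a2 = en.mww_class_test(ranked, others).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_empty_group_skipped(self):
        ranked = [("d0", 1.0), ("d1", 0.5)]
        assert en.mww_class_test(ranked, set()) is None
        assert en.mww_class_test(ranked, {"d0", "d1"}) is None


class TestAllClasses:
    def _records(self):
        recs = []
        for i in range(12):
            codes = {"N05AB01"} if i < 6 else {"G03XA05"}
            if i == 0:
                codes.add("G03XA99")  # multi-class drug
            recs.append(DrugRecord(f"d{i}", set(), codes, []))
        return recs

    def test_drug_with_two_codes_in_both_level2_classes(self):
        members = en.class_memberships(self._records(), levels=(2,))
        assert "d0" in members[(2, "N05")]
        assert "d0" in members[(2, "G03")]

    def test_small_classes_skipped_and_not_counted(self):
        ranked = [(f"d{i}", 12.0 - i) for i in range(12)]
        _, n = en.test_all_classes(ranked, self._records(), levels=(2,),
                                   min_class_size=7)
        assert n == 1  # G03 has 7 members (d0 + d6..d11), N05 only 6

    def test_membership_matches_prefix_oracle(self, small_study, rng):
        from gwas2drug import drugsets as ds
        names = sorted(small_study.interactions["drug_name"].unique())
        recs = ds.map_drugs_to_atc(names, small_study.name_to_cid,
                                   small_study.cid_to_atc)
        got = en.class_memberships(recs)
        for (lvl, code), members in got.items():
            w = en.ATC_LEVEL_CHARS[lvl]
            assert len(code) == w
            expect = {r.atc_name for r in recs
                      if any(c[:w] == code for c in r.atc_codes)}
            assert members == expect

    def test_bonferroni_and_fdr_flags(self):
        ranked = [(f"d{i}", 12.0 - i) for i in range(12)]
        results, n = en.test_all_classes(ranked, self._records(), levels=(2,),
                                         min_class_size=3)
        assert n == len(results) == 2
        for r in results:
            assert r.q_value >= r.p_mww
            assert r.bonferroni_sig == (r.p_mww <= 0.05 / n)


class TestBhFdr:
    def test_hand_evaluated_step_up(self):
        q = en.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_single_p_passthrough(self):
        np.testing.assert_allclose(en.bh_fdr(np.array([0.3])), [0.3])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=30)
        q = en.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)
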