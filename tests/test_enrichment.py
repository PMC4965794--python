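from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from _oracles import hommel_closed_testing, hypergeom_pvalue_enum, hypergeom_pvalue_exact
from esnpo import builder, enrichment
from esnpo.builder import SnpTermAssociation
from esnpo.enrichment import ContingencyCounts


def make_esnpo(term_snps: dict[str, set[str]], ns="BP"):
    assocs = [
        SnpTermAssociation(s, t, ns, frozenset({"g"}), frozenset({"x"}))
        for t, snps in term_snps.items()
        for s in snps
    ]
    return builder.Esnpo(assocs)


class TestContingency:
    def test_counting(self):
        universe = {f"rs{i}" for i in range(10)}
        term_snps = {"T:1": {"rs0", "rs1", "rs2"}, "T:0": universe}
        e = make_esnpo(term_snps)
        query = {"rs0", "rs1", "rs5", "rs6", "rsX", "rsY"}  # 4 in universe
        c = enrichment.make_contingency(e, query, "T:1")
        assert (c.N, c.M, c.n, c.m) == (10, 4, 3, 2)

    def test_disjoint_query(self):
        e = make_esnpo({"T:1": {"rs1", "rs2"}})
        c = enrichment.make_contingency(e, {"zz"}, "T:1")
        assert (c.M, c.m) == (0, 0)

    def test_query_equals_universe_saturates(self):
        e = make_esnpo({"T:1": {"rs1", "rs2"}, "T:2": {"rs2", "rs3"}})
        c = enrichment.make_contingency(e, e.universe, "T:1")
        assert (c.N, c.M, c.n, c.m) == (3, 3, 2, 2)

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            enrichment.make_contingency(make_esnpo({"T:1": {"rs1"}}), {"rs1"}, "T:9")

    @pytest.mark.parametrize(
        "N,M,n,m",
        [(10, 4, 3, 4), (10, 11, 3, 0), (5, 2, 2, -1), (10, 4, 4, 0)],
    )
    def test_invariant_violations_rejected(self, N, M, n, m):
        # last case: m=0 < max(0, n+M-N)=0 is fine -> adjust to a violating one
        if (N, M, n, m) == (10, 4, 4, 0):
            N, M, n, m = 6, 4, 4, 1  # m < n+M-N = 2
        with pytest.raises(ValueError):
            ContingencyCounts(N, M, n, m)


class TestHypergeomPvalue:
    def test_frozen_small_cases(self):
        # all 4 query SNPs drawn in a 4-of-10 draw with 5 query SNPs: 5/210
        assert enrichment.hypergeom_pvalue(ContingencyCounts(10, 5, 4, 4)) == pytest.approx(
            5 / 210, abs=1e-12
        )
        # C(3,3)C(3,0)/C(6,3) = 1/20
        assert enrichment.hypergeom_pvalue(ContingencyCounts(6, 3, 3, 3)) == pytest.approx(
            0.05, abs=1e-12
        )

    def test_m_zero_gives_one(self):
        assert enrichment.hypergeom_pvalue(ContingencyCounts(100, 10, 5, 0)) == 1.0

    def test_matches_literal_enumeration(self):
        for N, M, n, m in [(8, 3, 4, 2), (9, 5, 3, 1), (10, 5, 4, 4), (7, 7, 3, 3)]:
            expected = float(hypergeom_pvalue_enum(N, M, n, m))
            got = enrichment.hypergeom_pvalue(ContingencyCounts(N, M, n, m))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_m(self):
        ps = [
            enrichment.hypergeom_pvalue(ContingencyCounts(50, 10, 8, m))
            for m in range(0, 9)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pmf_sums_to_one_small_universes(self):
        for N in range(1, 26, 6):
            for M in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n + M - N), min(M, n)
                    total = sum(
                        float(hypergeom.pmf(k, N, M, n)) for k in range(lo, hi + 1)
                    )
                    assert total == pytest.approx(1.0, abs=1e-9)

    @given(
        st.integers(1, 500).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            ).flatmap(
                lambda t: st.tuples(
                    st.just(t),
                    st.integers(max(0, t[2] + t[1] - t[0]), min(t[1], t[2])),
                )
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_scipy_survival_function(self, params):
        """Independent cross-check against scipy's hypergeometric tail."""
        (N, M, n), m = params
        c = ContingencyCounts(N, M, n, m)
        expected = float(hypergeom.sf(m - 1, N, M, n))
        assert enrichment.hypergeom_pvalue(c) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_large_counts_do_not_overflow(self):
        c = ContingencyCounts(400_000, 2_000, 50_000, 400)
        p = enrichment.hypergeom_pvalue(c)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(hypergeom.sf(399, 400_000, 2_000, 50_000)), rel=1e-9)


class TestAdjustPvalues:
    def test_bonferroni_multiplies_by_family_size(self):
        assert enrichment.adjust_pvalues([0.01, 0.2], "bonferroni") == pytest.approx([0.02, 0.4])

    def test_bh_step_up_by_hand(self):
        got = enrichment.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_holm_step_down_by_hand(self):
        got = enrichment.adjust_pvalues([0.04, 0.01, 0.03], "holm")
        assert got == pytest.approx([0.06, 0.03, 0.06])

    def test_fdr_alias_and_none(self):
        p = [0.2, 0.01]
        assert enrichment.adjust_pvalues(p, "fdr") == pytest.approx(
            enrichment.adjust_pvalues(p, "BH")
        )
        assert enrichment.adjust_pvalues(p, "none") == pytest.approx(p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment.adjust_pvalues([0.5, 1.2], "BH")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=150, deadline=None)
    def test_pointwise_orderings(self, ps):
        raw = np.array(ps)
        adj = {
            m: enrichment.adjust_pvalues(ps, m)
            for m in ("bonferroni", "holm", "hochberg", "hommel", "BH", "BY")
        }
        for m, a in adj.items():
            assert np.all(a >= raw - 1e-12), m
            assert np.all(a <= 1.0 + 1e-12), m
        assert np.all(adj["bonferroni"] >= adj["holm"] - 1e-12)
        assert np.all(adj["holm"] >= adj["hochberg"] - 1e-12)
        assert np.all(adj["hochberg"] >= adj["hommel"] - 1e-12)
        assert np.all(adj["BY"] >= adj["BH"] - 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_hommel_matches_closed_testing_bruteforce(self, ps):
        got = enrichment.adjust_pvalues(ps, "hommel")
        expected = hommel_closed_testing(ps)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "method,sm_name",
        [
            ("bonferroni", "bonferroni"),
            ("holm", "holm"),
            ("hochberg", "simes-hochberg"),
            ("hommel", "hommel"),
            ("BH", "fdr_bh"),
            ("BY", "fdr_by"),
        ],
    )
    def test_agrees_with_statsmodels(self, method, sm_name):
        """Independent cross-check against statsmodels.multipletests."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2016)
        for _ in range(20):
            k = int(rng.integers(1, 40))
            ps = rng.uniform(size=k)
            expected = multipletests(ps, method=sm_name)[1]
            got = enrichment.adjust_pvalues(ps, method)
            assert got == pytest.approx(expected, abs=1e-10)


class TestRunEnrichment:
    def universe_esnpo(self):
        rng = np.random.default_rng(5)
        universe = [f"rs{i}" for i in range(40)]
        term_snps = {"T:hit": set(universe[:8])}
        for j in range(9):
            term_snps[f"T:null{j}"] = set(
                rng.choice(universe, size=10, replace=False)
            )
        return make_esnpo(term_snps), universe

    def test_planted_term_ranks_first(self):
        e, universe = self.universe_esnpo()
        run = enrichment.run_enrichment(e, universe[:8] + universe[30:33], method="BH", alpha=0.01)
        assert run.results[0].term == "T:hit"
        assert run.results[0].significant

    def test_query_equal_universe_gives_p_one_everywhere(self):
        e, universe = self.universe_esnpo()
        run = enrichment.run_enrichment(e, universe, method="none", alpha=0.5)
        assert all(r.p == 1.0 for r in run.results)

    def test_family_is_touched_terms_only(self):
        e = make_esnpo({"T:1": {"rs1", "rs2"}, "T:2": {"rs3"}})
        run = enrichment.run_enrichment(e, ["rs1"], method="none", alpha=1.0)
        assert [r.term for r in run.results] == ["T:1"]
        run_all = enrichment.run_enrichment(e, ["rs1"], method="none", alpha=1.0, test_all_terms=True)
        assert {r.term for r in run_all.results} == {"T:1", "T:2"}

    def test_all_touched_terms_returned_with_no_adjustment(self):
        e, universe = self.universe_esnpo()
        query = universe[:5]
        run = enrichment.run_enrichment(e, query, method="none", alpha=1.0)
        touched = {
            t for t, snps in e.term_index.items() if snps & set(query)
        }
        assert {r.term for r in run.results} == touched

    def test_significance_flag_matches_definition(self):
        e, universe = self.universe_esnpo()
        run = enrichment.run_enrichment(e, universe[:8], method="BH", alpha=0.01)
        for r in run.results:
            assert r.significant == (r.p_adj < 0.01)
            assert r.p_adj >= r.p - 1e-15

    def test_dropped_query_snps_reported(self):
        e, universe = self.universe_esnpo()
        run = enrichment.run_enrichment(e, universe[:3] + ["rsX", "rsY"], method="BH")
        assert run.n_query_dropped == 2
        assert run.dropped_snps == {"rsX", "rsY"}
        assert run.n_query_in_universe == 3

    def test_disjoint_query_is_an_error(self):
        e, _ = self.universe_esnpo()
        with pytest.raises(ValueError, match="disjoint"):
            enrichment.run_enrichment(e, ["zz1", "zz2"])

    def test_sorted_by_p_with_term_tiebreak(self):
        e, universe = self.universe_esnpo()
        run = enrichment.run_enrichment(e, universe[:10], method="none", alpha=1.0)
        keys = [(r.p, r.term) for r in run.results]
        assert keys == sorted(keys)
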