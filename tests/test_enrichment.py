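from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mima
from mima.containers import PathwayCollection
from mima.enrichment import (
    bh_adjust,
    fisher_overlap,
    make_ranking,
    ora,
    overlap_percentage,
    pathway_score,
    preranked_gsea,
    rank_metric,
    score_correlation,
)
from mima.errors import ConfigurationError
from tests.conftest import hypergeom_tail_enum


class TestFisherOverlap:
    def test_disjoint_sets_not_enriched(self):
        universe = [f"g{i}" for i in range(10)]
        r = fisher_overlap(universe[:3], universe[3:6], universe)
        assert r.a == 0
        assert r.p_value >= 0.5

    def test_identical_sets_match_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        A = set(universe[:5])
        r = fisher_overlap(A, A, universe)
        assert r.p_value == pytest.approx(hypergeom_tail_enum(5, 100, 5, 5), abs=1e-12)

    def test_universe_exactly_covered(self):
        r = fisher_overlap({"a", "b"}, {"b", "c"}, {"a", "b", "c"})
        assert r.d == 0
        assert 0 < r.p_value <= 1

    def test_contingency_sums_to_universe(self):
        universe = [f"g{i}" for i in range(30)]
        r = fisher_overlap(universe[:8], universe[5:17], universe)
        assert r.a + r.b + r.c + r.d == 30

    def test_rejects_non_subset(self):
        with pytest.raises(ConfigurationError):
            fisher_overlap({"x"}, {"a"}, {"a", "b"})
        with pytest.raises(ConfigurationError):
            fisher_overlap({"a"}, {"a"}, set())

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_p_matches_hypergeometric_tail(self, data):
        n = data.draw(st.integers(2, 30))
        universe = [f"g{i}" for i in range(n)]
        ka = data.draw(st.integers(0, n))
        kb = data.draw(st.integers(0, n))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        A = set(rng.choice(universe, ka, replace=False))
        B = set(rng.choice(universe, kb, replace=False))
        r = fisher_overlap(A, B, universe)
        assert r.p_value == pytest.approx(hypergeom_tail_enum(r.a, n, ka, kb), abs=1e-10)


class TestBhAdjust:
    def test_single_value_passthrough(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_permutation_equivariance_and_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=50)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), ours[perm], atol=1e-12)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(1e-5, 1, 40))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj >= p).all() and (adj <= 1).all()

    def test_domain_checked(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.0, 0.5])


class TestRankMetric:
    def test_signed_logp(self):
        assert rank_metric([2.0], [0.01], "signed_logp")[0] == pytest.approx(2.0)
        assert rank_metric([-1.0], [1.0], "signed_logp")[0] == 0.0

    def test_lfc_times_logp(self):
        assert rank_metric([-0.5], [0.01], "lfc_times_logp")[0] == pytest.approx(-1.0)
        assert rank_metric([3.0], [1.0], "lfc_times_logp")[0] == 0.0

    def test_stat_mode_passthrough(self):
        np.testing.assert_allclose(rank_metric(None, None, "stat", stat=[1.5, -2.0]), [1.5, -2.0])

    def test_zero_p_clamped_not_fatal(self):
        out = rank_metric([1.0], [0.0], "signed_logp")
        assert np.isfinite(out[0]) and out[0] > 300


class TestPrerankedGsea:
    genes8 = list("abcdefgh")
    scores8 = np.array([4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0])

    def _exact_es_distribution(self, set_size=3):
        ranking = make_ranking(self.genes8, self.scores8)
        absw = np.abs(ranking.values)

        def es(pos):
            mask = np.zeros(8, bool)
            mask[list(pos)] = True
            w = np.where(mask, absw, 0.0)
            run = np.cumsum(w) / w.sum() - np.cumsum(~mask) / (8 - set_size)
            return run[np.argmax(np.abs(run))]

        return ranking, es, [es(c) for c in combinations(range(8), set_size)]

    def test_top_block_set_is_significant(self):
        genes = [f"g{i}" for i in range(100)]
        ranking = make_ranking(genes, np.linspace(3, -3, 100))
        res = preranked_gsea(
            ranking, PathwayCollection(sets={"top": genes[:5]}), n_perm=1000, seed=0
        )[0]
        assert res.es > 0
        assert res.p_value < 0.05

    def test_permutation_p_matches_full_enumeration(self):
        ranking, es, all_es = self._exact_es_distribution()
        obs = es([0, 1, 2])
        exact_p = sum(1 for e in all_es if e >= obs) / len(all_es)
        res = preranked_gsea(
            ranking, PathwayCollection(sets={"s": ["a", "b", "c"]}), n_perm=20000, seed=1
        )[0]
        assert res.es == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(exact_p, abs=0.01)

    def test_reversed_ranking_negates_es(self):
        genes = [f"g{i}" for i in range(40)]
        scores = np.linspace(2, -2, 40)
        sets = PathwayCollection(sets={"s1": genes[3:9], "s2": genes[20:26]})
        fwd = {r.pathway: r.es for r in preranked_gsea(make_ranking(genes, scores), sets, n_perm=100, seed=0)}
        rev = {r.pathway: r.es for r in preranked_gsea(make_ranking(genes, -scores), sets, n_perm=100, seed=0)}
        for name in fwd:
            assert rev[name] == pytest.approx(-fwd[name], abs=1e-9)

    def test_whole_ranking_set_dropped_with_warning(self):
        ranking = make_ranking(self.genes8, self.scores8)
        with pytest.warns(UserWarning):
            res = preranked_gsea(
                ranking, PathwayCollection(sets={"all": self.genes8}), n_perm=100, seed=0
            )
        assert res == []

    def test_low_n_perm_rejected(self):
        ranking = make_ranking(self.genes8, self.scores8)
        with pytest.raises(ConfigurationError):
            preranked_gsea(ranking, PathwayCollection(sets={"s": ["a"]}), n_perm=50)

    def test_es_matches_gseapy_reference(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        scores = np.sort(rng.normal(size=60))[::-1]
        ranking = make_ranking(genes, scores)
        sets = {"sA": genes[2:10], "sB": genes[40:52]}
        ours = {r.pathway: r.es for r in preranked_gsea(ranking, PathwayCollection(sets=sets), n_perm=100, seed=0)}
        rnk = pd.DataFrame({"gene": ranking.index, "score": ranking.values})
        pre = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=10, min_size=2, max_size=60,
            weight=1.0, seed=1, outdir=None, no_plot=True, threads=1,
        )
        for name, es in ours.items():
            assert es == pytest.approx(pre.results[name]["es"], abs=1e-6)


class TestPathwayScores:
    def test_worked_values(self):
        assert pathway_score(0.01, -1.3) == pytest.approx(-2.0)
        assert pathway_score(1.0, 2.0) == 0.0
        assert pathway_score(0.001, 0.2) == pytest.approx(3.0)
        assert pathway_score(0.5, 0.0) == 0.0

    def test_domain_checks(self):
        with pytest.raises(ConfigurationError):
            pathway_score(0.0, 1.0)
        with pytest.raises(ConfigurationError):
            pathway_score(0.5, np.inf)

    def test_identical_scores_correlate_perfectly(self):
        s = pd.Series([1.0, -2.0, 3.0, 0.5], index=list("wxyz"))
        r, slope, n = score_correlation(s, s)
        assert (r, slope, n) == (pytest.approx(1.0), pytest.approx(1.0), 4)

    def test_doubled_scores_give_slope_two(self):
        s = pd.Series([1.0, -2.0, 3.0, 0.5], index=list("wxyz"))
        r, slope, _ = score_correlation(s, 2 * s)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_independent_scores_have_small_r(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = [f"p{i}" for i in range(200)]
            a = pd.Series(rng.normal(size=200), index=idx)
            b = pd.Series(rng.normal(size=200), index=idx)
            r, _, _ = score_correlation(a, b)
            hits += abs(r) < 0.2
        assert hits >= 19

    def test_too_few_matched_pathways_rejected(self):
        a = pd.Series([1.0, 2.0], index=["p1", "p2"])
        with pytest.raises(ConfigurationError):
            score_correlation(a, a)


class TestOra:
    def test_query_identical_set_ranks_first(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:5]
        sets = PathwayCollection(sets={"match": list(query), "other": universe[10:14]})
        table = ora(query, sets, universe)
        assert table.iloc[0]["pathway"] == "match"

    def test_disjoint_set_not_significant(self):
        universe = [f"g{i}" for i in range(20)]
        sets = PathwayCollection(sets={"s": universe[10:14]})
        table = ora(universe[:5], sets, universe)
        assert table.iloc[0]["p"] > 0.2

    def test_p_matches_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:5]
        annotation = universe[2:6]  # overlap 3 with the query
        table = ora(query, PathwayCollection(sets={"s": annotation}), universe)
        assert table.iloc[0]["overlap"] == 3
        assert table.iloc[0]["p"] == pytest.approx(hypergeom_tail_enum(3, 20, 4, 5), abs=1e-12)

    def test_empty_query_rejected(self):
        with pytest.raises(ConfigurationError):
            ora([], PathwayCollection(sets={"s": ["a"]}), ["a"])


class TestOverlapPercentage:
    def test_subset_is_100(self):
        assert overlap_percentage({"a", "b"}, {"a", "b", "c"}) == 100.0

    def test_disjoint_is_0(self):
        assert overlap_percentage({"a"}, {"b"}) == 0.0

    def test_fractional(self):
        A = {f"g{i}" for i in range(10)}
        B = {"g0", "g1", "g2", "x"}
        assert overlap_percentage(A, B) == pytest.approx(30.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            overlap_percentage(set(), {"a"})
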