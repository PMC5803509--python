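"""Enrichment statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import plstx as px
from plstx.enrichment import (_mhg_exact_p, _tail_grid, competitive_geneset_comparison,
                              enrichment_ratio, geneset_weight_enrichment, go_enrichment,
                              hypergeom_tail, mhg_scan, overlap_test,
                              weight_foldchange_correlation)
from plstx.synth import GeneSetCollection


class TestHypergeomTail:
    def test_zero_overlap_certain(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_complete_overlap_enumeration(self):
        # all 5 draws hit the 5 marked of 10: 1 / C(10,5) = 1/252
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    @given(st.integers(5, 40), st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_pmf_sum_oracle(self, N, data):
        B = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        b = data.draw(st.integers(0, min(n, B)))
        oracle = sum(stats.hypergeom.pmf(k, N, B, n) for k in range(b, min(n, B) + 1))
        assert hypergeom_tail(b, n, B, N) == pytest.approx(min(oracle, 1.0), abs=1e-12)

    def test_matches_scipy_sf(self):
        for (b, n, B, N) in [(3, 10, 20, 100), (1, 5, 5, 50), (8, 12, 30, 60)]:
            assert hypergeom_tail(b, n, B, N) == pytest.approx(
                stats.hypergeom.sf(b - 1, N, B, n), rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(6, 5, 5, 10)


class TestEnrichmentRatio:
    def test_no_enrichment(self):
        assert enrichment_ratio(1, 4, 5, 20) == 1.0

    def test_twofold(self):
        assert enrichment_ratio(2, 4, 5, 20) == 2.0

    def test_full_sets(self):
        assert enrichment_ratio(4, 4, 20, 20) == 1.0

    def test_zero_division_rejected(self):
        with pytest.raises(ZeroDivisionError):
            enrichment_ratio(0, 0, 5, 20)


def _enum_min_tails(N, K):
    """Min hypergeometric tail for every C(N,K) placement (exhaustive oracle)."""
    grid = _tail_grid(N, K)
    mins = []
    for pos in itertools.combinations(range(N), K):
        member = np.zeros(N, dtype=bool)
        member[list(pos)] = True
        b = np.cumsum(member)
        mins.append(grid[np.arange(1, N + 1), b].min())
    return np.asarray(mins)


class TestMHG:
    def test_top_concentrated_example(self):
        r = mhg_scan([1, 1, 0, 0, 0, 0])
        assert r.n_star == 2 and r.b_star == 2
        assert r.score == pytest.approx(1 / 15)
        assert r.p_value == pytest.approx(1 / 15)

    def test_bottom_members_worst_case(self):
        bottom = mhg_scan([0] * 8 + [1, 1])
        top = mhg_scan([1, 1] + [0] * 8)
        assert bottom.score >= top.score
        assert bottom.p_value > 0.9

    @pytest.mark.parametrize("N,K", [(6, 2), (8, 3), (10, 4), (12, 4)])
    def test_dp_matches_enumeration(self, N, K):
        mins = _enum_min_tails(N, K)
        rng = np.random.default_rng(0)
        for _ in range(5):
            member = np.zeros(N, dtype=bool)
            member[rng.choice(N, K, replace=False)] = True
            r = mhg_scan(member)
            oracle = (mins <= r.score * (1 + 1e-12)).mean()
            assert r.p_value == pytest.approx(oracle, abs=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mhg_scan([0, 0, 0])

    def test_exact_p_tiny_values_positive(self):
        member = np.zeros(500, dtype=bool)
        member[:40] = True
        p = mhg_scan(member).p_value
        assert 0 < p < 1e-30


@pytest.fixture(scope="module")
def ranked_and_sets(small_fit):
    ds, _, _, res = small_fit
    return res.gene_ranking(1), ds.gene_sets


class TestGoEnrichment:

    def test_planted_term_first_and_significant(self, ranked_and_sets):
        ranked, sets = ranked_and_sets
        out = go_enrichment(ranked, sets)
        assert out.iloc[0]["term_id"] == "PLANTED:primary"
        assert out.iloc[0]["q_value"] < 0.05

    def test_term_size_filter(self, ranked_and_sets):
        ranked, sets = ranked_and_sets
        big = GeneSetCollection(sets={**sets.sets, "BIG": set(ranked["gene"])},
                                descriptions=dict(sets.descriptions))
        out = go_enrichment(ranked, big, max_term_size=250)
        assert "BIG" not in set(out["term_id"])

    def test_duplicate_member_sets_collapsed(self, ranked_and_sets):
        ranked, sets = ranked_and_sets
        dup = GeneSetCollection(sets={"A": set(list(sets.sets["T0001"])),
                                      "B": set(list(sets.sets["T0001"]))})
        out = go_enrichment(ranked, dup)
        assert len(out) == 1

    def test_enrichment_ratio_identity(self, ranked_and_sets):
        ranked, sets = ranked_and_sets
        out = go_enrichment(ranked, sets)
        for row in out.itertuples():
            if row.b:
                assert row.enrichment == pytest.approx(
                    (row.b / row.n) / (row.B / row.N), rel=1e-12)

    def test_random_terms_rarely_significant(self):
        """BH-corrected q of unplanted terms stays above 0.05 almost always."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(200)]
        hits = 0
        runs = 30
        for seed in range(runs):
            ranked = list(rng.permutation(genes))
            sets = px.generate_gene_sets(genes, 10, (10, 30), seed=seed)
            out = go_enrichment(ranked, sets)
            hits += int((out["q_value"] < 0.05).any())
        assert hits <= max(2, int(0.05 * runs) + 2)

    def test_overlap_removed_preserves_top_term(self):
        """Dropping the genes shared by two analyses' top lists keeps each
        analysis's planted term on top (the two planted profiles load
        disjoint gene pools, so the shared top genes are incidental)."""
        import plstx as px
        from conftest import fit_corticostriatal
        from plstx.connectome import (atrophy_scores, consensus_mask,
                                      group_profiles)

        cohort = px.CohortSpec(n_patients=14, n_controls=14, seed=2,
                               effect_size_by_class={"corticostriatal": 0.3,
                                                     "interhemispheric": 0.2,
                                                     "intrahemispheric": 0.3})
        ds = px.generate_dataset(seed=31, n_cortical_per_hemisphere=17,
                                 n_genes=600, n_donors=3, cohort=cohort,
                                 two_profile=True)
        _, expr, res_cs = fit_corticostriatal(ds)
        controls = [c for c in ds.connectomes if c.group == "control"]
        mask = consensus_mask(controls, 0.75)
        prof = group_profiles(ds.connectomes, ds.atlas, mask, timepoint=24.0)
        atrophy = atrophy_scores(prof["patient"], prof["control"])
        res_intra = px.ExpressionAtrophyPLS(
            expr, atrophy.values[["intrahemispheric"]], n_components=2).fit()

        top_cs = set(res_cs.gene_ranking(1)["gene"][:100])
        top_intra = set(res_intra.gene_ranking(1)["gene"][:100])
        overlap = top_cs & top_intra
        kept = res_cs.gene_ranking(1)
        kept = kept[~kept["gene"].isin(overlap)]
        out = go_enrichment(kept, ds.gene_sets)
        assert out.iloc[0]["term_id"] == "PLANTED:primary"

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(size=100)
            from statsmodels.stats.multitest import multipletests
            q = multipletests(p, method="fdr_bh")[1]
            # from-scratch step-up oracle
            order = np.argsort(p)
            m = len(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(adj, 1.0)
            np.testing.assert_allclose(q, oracle, atol=1e-12)


class TestWeightEnrichment:
    @pytest.fixture
    def weights(self):
        rng = np.random.default_rng(2)
        return pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])

    def test_top_k_target_minimal_p(self, weights):
        target = list(weights.sort_values(ascending=False).index[:10])
        out = geneset_weight_enrichment(weights, target, n_perm=99, seed=0)
        assert out.p_value == pytest.approx(1 / 100)

    def test_p_in_unit_interval(self, weights):
        out = geneset_weight_enrichment(weights, list(weights.index[:15]),
                                        n_perm=49, seed=1)
        assert 0 < out.p_value <= 1

    def test_empty_target_rejected(self, weights):
        with pytest.raises(ValueError):
            geneset_weight_enrichment(weights, ["not_a_gene"], n_perm=10, seed=0)


class TestCompetitive:
    @pytest.fixture
    def weights(self):
        rng = np.random.default_rng(3)
        return pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])

    def test_target_beats_all(self, weights):
        target = list(weights.sort_values(ascending=False).index[:10])
        rng = np.random.default_rng(0)
        comps = [list(rng.choice(weights.index, 10, replace=False)) for _ in range(25)]
        out = competitive_geneset_comparison(weights, target, comps)
        assert out.p_value == 0.0
        assert out.p_bound == pytest.approx(1 / 25)

    def test_target_from_pool_uniform(self, weights):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(50):
            comps = [list(rng.choice(weights.index, 10, replace=False))
                     for _ in range(40)]
            target = list(rng.choice(weights.index, 10, replace=False))
            ps.append(competitive_geneset_comparison(weights, target, comps).p_value)
        assert 0.3 < np.mean(ps) < 0.7

    def test_size_mismatch_warns_and_matches(self, weights):
        rng = np.random.default_rng(2)
        target = list(weights.index[:10])
        comps = [list(rng.choice(weights.index, 20, replace=False)) for _ in range(20)]
        with pytest.warns(UserWarning, match="size-matched"):
            competitive_geneset_comparison(weights, target, comps)

    def test_too_few_competitors_rejected(self, weights):
        with pytest.raises(ValueError):
            competitive_geneset_comparison(weights, list(weights.index[:5]),
                                           [list(weights.index[5:10])])


class TestOverlap:
    def test_disjoint_p_one(self):
        b, p = overlap_test(["a", "b"], ["c", "d"], 10)
        assert b == 0 and p == 1.0

    def test_identical_lists_enumeration(self):
        genes = list("abcde")
        b, p = overlap_test(genes, genes, 10)
        assert b == 5
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_symmetric(self):
        a, bl = ["a", "b", "c"], ["b", "c", "d", "e"]
        b1, p1 = overlap_test(a, bl, 20)
        b2, p2 = overlap_test(bl, a, 20)
        assert b1 == b2
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_duplicates_warn(self):
        with pytest.warns(UserWarning, match="dedup"):
            overlap_test(["a", "a", "b"], ["b"], 10)


class TestWeightFoldchange:
    def test_perfect_anti_ranking(self):
        w = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        fc = pd.DataFrame({"gene": w.index, "log2fc": -np.arange(20.0)})
        rho, p, n = weight_foldchange_correlation(w, fc)
        assert rho == pytest.approx(-1.0)
        assert n == 20

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        w = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        fc = pd.DataFrame({"gene": w.index, "log2fc": rng.normal(size=50)})
        rho, _, _ = weight_foldchange_correlation(w, fc)
        oracle = np.corrcoef(stats.rankdata(w), stats.rankdata(fc["log2fc"]))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_shared_rejected(self):
        w = pd.Series([1.0, 2.0], index=["a", "b"])
        fc = pd.DataFrame({"gene": ["a", "b"], "log2fc": [0.1, 0.2]})
        with pytest.raises(ValueError):
            weight_foldchange_correlation(w, fc)

    def test_generator_target_recovered(self, small_dataset):
        ds = small_dataset
        w = ds.truth.gene_loadings
        rho, _, n = weight_foldchange_correlation(w, ds.foldchange)
        assert n == len(w)
        assert rho == pytest.approx(-0.23, abs=0.02)
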