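"""WRFEN feature selection: the two base rankings and their
exponential-Pearson weighted fusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wrfenboost.wrfen import (
    FusedRanking,
    GeneRanking,
    en_rank,
    fuse_rankings,
    rf_rank,
    select_genes,
)

from conftest import make_dataset


def ranking(method, genes, pearson):
    return GeneRanking(
        method=method,
        genes=list(genes),
        importance=np.linspace(1.0, 0.1, len(genes)),
        validation_pearson=pearson,
    )


def brute_force_fuse(rf_genes, en_genes, r_rf, r_en):
    """Independent arithmetic path for the fused score."""
    w1, w2 = math.exp(r_rf), math.exp(r_en)
    rank1 = {g: i + 1 for i, g in enumerate(rf_genes)}
    rank2 = {g: i + 1 for i, g in enumerate(en_genes)}
    out = {}
    for g in set(rf_genes) | set(en_genes):
        a = rank1.get(g, len(rf_genes) + 1)
        b = rank2.get(g, len(en_genes) + 1)
        out[g] = (w1 * a + w2 * b) / (w1 + w2)
    return out


class TestFusion:
    def test_hand_computed_three_gene_example(self):
        rf = ranking("RF", ["g1", "g2", "g3"], 0.8)
        en = ranking("EN", ["g2", "g3", "g1"], 0.4)  # rank_EN: g1=3, g2=1, g3=2
        fused = fuse_rankings(rf, en)
        scores = dict(zip(fused.genes, fused.fused_score))
        assert scores["g1"] == pytest.approx(1.8026, abs=1e-4)
        assert scores["g2"] == pytest.approx(1.5987, abs=1e-4)
        assert scores["g3"] == pytest.approx(2.5986, abs=1e-4)
        assert fused.genes == ["g2", "g1", "g3"]

    def test_identical_rankings_preserved_for_any_pearsons(self):
        for r_rf, r_en in [(0.9, 0.1), (-0.5, 0.5), (0.3, 0.3)]:
            rf = ranking("RF", ["a", "b", "c", "d"], r_rf)
            en = ranking("EN", ["a", "b", "c", "d"], r_en)
            assert fuse_rankings(rf, en).genes == ["a", "b", "c", "d"]

    def test_equal_pearson_reduces_to_mean_rank(self):
        rf = ranking("RF", ["a", "b", "c"], 0.6)
        en = ranking("EN", ["c", "a", "b"], 0.6)
        fused = fuse_rankings(rf, en)
        scores = dict(zip(fused.genes, fused.fused_score))
        assert scores["a"] == pytest.approx((1 + 2) / 2)
        assert scores["b"] == pytest.approx((2 + 3) / 2)
        assert scores["c"] == pytest.approx((3 + 1) / 2)

    def test_matches_brute_force_on_random_rankings(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(50):
            n1, n2 = rng.integers(2, 51, size=2)
            g1 = list(rng.permutation(genes)[:n1])
            g2 = list(rng.permutation(genes)[:n2])
            r1, r2 = rng.uniform(-1, 1, size=2)
            fused = fuse_rankings(ranking("RF", g1, r1), ranking("EN", g2, r2))
            expected = brute_force_fuse(g1, g2, r1, r2)
            for g, s in zip(fused.genes, fused.fused_score):
                assert abs(s - expected[g]) < 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(r1=st.floats(-1, 1), r2=st.floats(-1, 1), perm_seed=st.integers(0, 100))
    def test_fused_score_bounded_by_input_ranks(self, r1, r2, perm_seed):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(perm_seed)
        g2 = list(rng.permutation(genes))
        fused = fuse_rankings(ranking("RF", genes, r1), ranking("EN", g2, r2))
        rank_rf = {g: i + 1 for i, g in enumerate(genes)}
        rank_en = {g: i + 1 for i, g in enumerate(g2)}
        for g, s in zip(fused.genes, fused.fused_score):
            lo = min(rank_rf[g], rank_en[g])
            hi = max(rank_rf[g], rank_en[g])
            assert lo - 1e-12 <= s <= hi + 1e-12

    def test_raising_rf_pearson_pulls_scores_toward_rf_ranks(self):
        genes = [f"g{i}" for i in range(8)]
        g2 = genes[::-1]
        low = fuse_rankings(ranking("RF", genes, 0.1), ranking("EN", g2, 0.5))
        high = fuse_rankings(ranking("RF", genes, 0.9), ranking("EN", g2, 0.5))
        rank_rf = {g: i + 1 for i, g in enumerate(genes)}
        s_low = dict(zip(low.genes, low.fused_score))
        s_high = dict(zip(high.genes, high.fused_score))
        for g in genes:
            assert abs(s_high[g] - rank_rf[g]) <= abs(s_low[g] - rank_rf[g]) + 1e-12

    def test_selected_count_is_weighted_average_of_retained_counts(self):
        rf = ranking("RF", [f"g{i}" for i in range(10)], 0.5)
        en = ranking("EN", [f"g{i}" for i in range(4)], 0.5)
        assert fuse_rankings(rf, en).selected_count == 7

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            fuse_rankings(ranking("RF", [], 0.5), ranking("EN", ["a"], 0.5))


class TestRfRank:
    def test_target_equal_to_one_gene_puts_it_first(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 20))
        y = X[:, 7].copy()
        ds = make_dataset(X, y)
        for seed in range(5):
            assert rf_rank(ds, seed=seed).genes[0] == "g0008"

    def test_constant_gene_has_zero_importance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 10))
        X[:, 4] = 2.5
        y = X[:, 0] + 0.1 * rng.standard_normal(150)
        r = rf_rank(make_dataset(X, y), seed=0)
        assert "g0005" not in r.genes

    def test_constant_target_is_error(self):
        X = np.random.default_rng(4).standard_normal((50, 5))
        with pytest.raises(ValueError, match="constant"):
            rf_rank(make_dataset(X, np.ones(50)), seed=0)

    def test_pure_noise_validation_pearson_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 30))
        y = rng.standard_normal(500)
        r = rf_rank(make_dataset(X, y), seed=0)
        assert abs(r.validation_pearson) < 0.3

    def test_importance_non_increasing(self, planted_linear_dataset):
        r = rf_rank(planted_linear_dataset, seed=0)
        assert np.all(np.diff(r.importance) <= 0)


class TestEnRank:
    def test_dominant_gene_ranked_first(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((200, 15))
        y = 3.0 * X[:, 0] + 0.01 * rng.standard_normal(200)
        r = en_rank(make_dataset(X, y), seed=0)
        assert r.genes[0] == "g0001"
        assert r.validation_pearson > 0.99

    def test_duplicated_gene_shares_top_ranks(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 10))
        X[:, 1] = X[:, 0]  # exact duplicate
        y = 2.0 * X[:, 0] + 0.05 * rng.standard_normal(200)
        r = en_rank(make_dataset(X, y), l1_ratios=(0.1, 0.5), seed=0)
        assert set(r.genes[:2]) == {"g0001", "g0002"}

    def test_degenerate_grid_returns_that_pair(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(100)
        r = en_rank(make_dataset(X, y), l1_ratios=(0.5,), penalties=(0.3,), seed=0)
        assert r.params == {"l1_ratio": 0.5, "penalty": 0.3}

    def test_pure_noise_under_heavy_lasso_raises_empty_support(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)  # unrelated to X: full shrinkage at alpha=1
        with pytest.raises(ValueError, match="empty elastic-net support"):
            en_rank(make_dataset(X, y), penalties=(1.0,), l1_ratios=(1.0,), seed=0)


class TestSelectGenes:
    def fused(self, n=10):
        return FusedRanking(
            genes=[f"g{i}" for i in range(n)],
            fused_score=np.arange(1.0, n + 1),
            selected_count=4,
            rf_pearson=0.5,
            en_pearson=0.5,
        )

    def test_full_and_single(self):
        f = self.fused()
        assert select_genes(f, len(f)) == f.genes
        assert select_genes(f, 1) == ["g0"]

    def test_auto_uses_selected_count(self):
        assert len(select_genes(self.fused(), "auto")) == 4

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            select_genes(self.fused(), 0)
        with pytest.raises(ValueError):
            select_genes(self.fused(), 11)

    def test_column_permutation_does_not_change_selection(self, planted_linear_dataset):
        ds = planted_linear_dataset
        rf = rf_rank(ds, seed=1)
        en = en_rank(ds, seed=1)
        top = set(select_genes(fuse_rankings(rf, en), 5))

        perm = np.random.default_rng(11).permutation(ds.X.shape[1])
        ds2 = make_dataset(ds.X.to_numpy()[:, perm], ds.y.to_numpy())
        ds2.X.columns = [ds.X.columns[i] for i in perm]
        rf2 = rf_rank(ds2, seed=1)
        en2 = en_rank(ds2, seed=1)
        top2 = set(select_genes(fuse_rankings(rf2, en2), 5))
        assert top == top2
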