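import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import imgx
from imgx.enrichment import (
    bh_adjust,
    compute_specificity,
    ewce_test,
    hypergeom_overlap,
    matched_bins,
)


def spec_matrix(values, genes=None, types=None, rng_seed=0):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    types = types or [f"c{i}" for i in range(values.shape[1])]
    rng = np.random.default_rng(rng_seed)
    me = pd.DataFrame(values, index=genes, columns=types)
    length = pd.Series(rng.uniform(500, 5000, len(genes)), index=genes)
    gc = pd.Series(rng.uniform(0.3, 0.7, len(genes)), index=genes)
    return compute_specificity(me, length, gc)


class TestSpecificity:
    def test_exclusive_gene(self):
        S = spec_matrix([[2.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(S.values.iloc[0], [1.0, 0.0])

    def test_equal_expression_uniform(self):
        S = spec_matrix(np.ones((3, 4)))
        np.testing.assert_allclose(S.values.to_numpy(), 0.25)

    def test_marker_fold_formula(self):
        # fold 4 against 3 baseline types: 4 / (4 + 3) = 4/7
        S = spec_matrix([[4.0, 1, 1, 1]])
        assert S.values.iloc[0, 0] == pytest.approx(4 / 7)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        S = spec_matrix(rng.uniform(0.1, 3, (20, 5)))
        np.testing.assert_allclose(S.values.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_gene_dropped_and_listed(self):
        me = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["dead", "ok"], columns=["a", "b"])
        S = compute_specificity(me)
        assert S.dropped_genes == ("dead",)
        assert S.genes == ["ok"]


class TestMatchedBins:
    def test_uniform_covariates_balanced_bins(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(400)]
        length = pd.Series(rng.uniform(0, 1, 400), index=genes)
        gc = pd.Series(rng.uniform(0, 1, 400), index=genes)
        bins = matched_bins(genes, length, gc, n_bins=4)
        sizes = bins.value_counts()
        assert sizes.max() / sizes.min() <= 2

    def test_single_bin_degenerate(self):
        genes = ["a", "b", "c"]
        s = pd.Series([1.0, 2, 3], index=genes)
        bins = matched_bins(genes, s, s, n_bins=1)
        assert set(bins) == {0}

    def test_too_many_bins_rejected(self):
        genes = ["a", "b", "c"]
        s = pd.Series([1.0, 2, 3], index=genes)
        with pytest.raises(ValueError, match="bins"):
            matched_bins(genes, s, s, n_bins=10)

    def test_matched_null_draws_match_target_length(self):
        """Null lists drawn respecting bins track the target's mean length."""
        rng = np.random.default_rng(3)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        length = pd.Series(rng.uniform(500, 10_000, n), index=genes)
        gc = pd.Series(rng.uniform(0.3, 0.7, n), index=genes)
        # a long-transcript-biased target drawn from the upper length range
        target = list(rng.choice(length.sort_values().index[-150:], 20, replace=False))
        bins = matched_bins(genes, length, gc, n_bins=10)
        tb = bins.loc[target].value_counts()
        rngd = np.random.default_rng(4)
        means = []
        for _ in range(200):
            draw = []
            for b, m in tb.items():
                pool = bins.index[bins == b]
                draw += list(rngd.choice(pool, m, replace=False))
            means.append(length.loc[draw].mean())
        assert abs(np.mean(means) - length.loc[target].mean()) / length.loc[target].mean() < 0.1


class TestEWCE:
    def test_enumeration_oracle_small_instances(self):
        """Bootstrap p matches exhaustive enumeration on every tiny instance."""
        rng = np.random.default_rng(5)
        n_perm = 20_000
        for n_genes, n_types, t_size in [(4, 2, 1), (5, 3, 2), (6, 3, 2)]:
            me = rng.uniform(0.2, 2.0, (n_genes, n_types))
            S = spec_matrix(me, rng_seed=6)
            target = list(S.genes[:t_size])
            V = S.values.to_numpy()
            obs = V[:t_size].sum(axis=0)
            null = np.array(
                [V[list(c)].sum(axis=0) for c in itertools.combinations(range(n_genes), t_size)]
            )
            p_exact = (null >= obs[None, :]).mean(axis=0)
            res = ewce_test(target, S, n_perm=n_perm, seed=7, n_bins=1)
            p_boot = res.table["p"].to_numpy()
            p_pred = (1 + n_perm * p_exact) / (1 + n_perm)
            se = np.sqrt(np.maximum(p_exact * (1 - p_exact), 1e-12) / n_perm)
            assert np.all(np.abs(p_boot - p_pred) <= 3 * se + 1e-9)

    def test_flat_matrix_no_structure(self):
        S = spec_matrix(np.ones((40, 4)), rng_seed=8)
        res = ewce_test(list(S.genes[:5]), S, n_perm=2000, seed=9, n_bins=1)
        assert np.all(np.abs(res.table["sd_from_mean"]) < 1e-9)
        assert np.all(res.table["p"] > 0)

    def test_planted_markers_attain_minimal_p(self):
        spec = imgx.CellTypeSpec(n_celltypes=4, markers_per_celltype=8, marker_fold=4.0, seed=10)
        genes = [f"G{i:03d}" for i in range(600)]
        me, annot, degs = imgx.gen_celltype_reference(spec, genes)
        S = compute_specificity(me, annot["length_bp"], annot["gc"])
        markers = list(me.index[me["astrocyte"] == 4.0])
        res = ewce_test(markers, S, n_perm=5000, seed=11)
        assert res.table.loc["astrocyte", "p"] == pytest.approx(1 / 5001)
        assert res.table["sd_from_mean"].idxmax() == "astrocyte"

    def test_full_universe_statistic_is_column_sum(self):
        S = spec_matrix(np.random.default_rng(12).uniform(0.1, 1, (30, 3)), rng_seed=12)
        res = ewce_test(list(S.genes), S, n_perm=10, seed=0, n_bins=1)
        np.testing.assert_allclose(
            res.table["observed"].to_numpy(), S.values.sum(axis=0).to_numpy(), atol=1e-12
        )

    def test_null_target_p_uniform(self):
        rng = np.random.default_rng(13)
        S = spec_matrix(rng.uniform(0.1, 2, (60, 3)), rng_seed=14)
        ps = []
        for rep in range(500):
            target = list(rng.choice(S.genes, 5, replace=False))
            res = ewce_test(target, S, n_perm=1000, seed=500 + rep, n_bins=1)
            ps.append(res.table["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestHypergeom:
    def test_empty_lists(self):
        res = hypergeom_overlap([], [], [f"g{i}" for i in range(10)])
        assert res.k == 0 and res.p == 1.0

    def test_exact_enumeration_value(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)/C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        deg = universe[:5]
        target = universe[:4]
        res = hypergeom_overlap(target, deg, universe)
        assert res.p == pytest.approx(5 / 210, abs=1e-12)

    def test_expected_overlap_not_significant(self):
        # N=20, K=8, n=6: E[X]=2.4; k=2 must have p >= 0.3
        universe = [f"g{i}" for i in range(20)]
        deg = universe[:8]
        target = universe[6:12]  # overlap {6,7} -> k=2
        res = hypergeom_overlap(target, deg, universe)
        assert res.k == 2 and res.p >= 0.3

    def test_enumeration_oracle_all_small_instances(self):
        """Closed form matches brute-force enumeration for N <= 12."""
        rng = np.random.default_rng(15)
        for _ in range(20):
            N = int(rng.integers(4, 12))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = list(range(N))
            deg = set(universe[:K])
            target = set(rng.choice(universe, n, replace=False))
            k = len(target & deg)
            count = sum(
                1 for c in itertools.combinations(universe, n) if len(set(c) & deg) >= k
            )
            from math import comb

            res = hypergeom_overlap(
                [str(g) for g in target], [str(g) for g in deg], [str(g) for g in universe]
            )
            assert res.p == pytest.approx(count / comb(N, n), abs=1e-9)

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_overlap(["x"], ["a"], ["a", "b"])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_hand_worked_stepup(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_order_restored_and_bounds(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(p * len(p), 1.0) + 1e-15)
        # monotone in raw order
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_manual_stepup_rule(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=11)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            manual[order[rank]] = running
        np.testing.assert_allclose(bh_adjust(p), manual, atol=1e-12)
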