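"""Module detection, eigengene merging, and permutation preservation."""

import numpy as np
import pandas as pd
import pytest

from xenonet import (
    AdjacencyParams,
    adjacency_connectivity,
    correlation_matrix,
    detect_modules,
    merge_modules,
    module_eigengenes,
    preservation_zsummary,
    select_top_connected,
    tom_similarity,
    zsummary_bin,
)
from xenonet.modules import GREY


def expr_frame(array, prefix="s"):
    array = np.asarray(array, float)
    return pd.DataFrame(
        array,
        index=[f"g{i:03d}" for i in range(array.shape[0])],
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )


def block_expr(rng, block_sizes, loading=0.9, noise=0.5, n=100):
    rows = []
    for size in block_sizes:
        f = rng.standard_normal(n)
        rows.append(loading * f + noise * rng.standard_normal((size, n)))
    return expr_frame(np.vstack(rows))


class TestSelectTopConnected:
    def make(self, k):
        genes = [f"g{i}" for i in range(len(k))]
        return pd.DataFrame({"k_raw": k, "k_norm": np.asarray(k) / max(k)}, index=genes)

    def test_identical_rankings_union_is_m(self):
        t = self.make([5, 4, 3, 2, 1])
        assert len(select_top_connected(t, t, m=3)) == 3

    def test_disjoint_rankings_union_is_2m(self):
        tc = self.make([5, 4, 1, 1, 1, 1])
        tt = self.make([1, 1, 1, 1, 4, 5])
        assert select_top_connected(tc, tt, m=2) == ["g0", "g1", "g4", "g5"]

    def test_m_larger_than_gene_count_takes_all(self):
        t = self.make([3, 2, 1])
        assert len(select_top_connected(t, t, m=100)) == 3

    def test_tie_at_rank_m_breaks_lexicographically(self):
        t = self.make([5, 2, 2, 2])
        assert select_top_connected(t, t, m=2) == ["g0", "g1"]

    def test_invalid_m_raises(self):
        t = self.make([1])
        with pytest.raises(ValueError):
            select_top_connected(t, t, m=0)


class TestTomSimilarity:
    def test_no_shared_neighbors_zero(self):
        adj = pd.DataFrame(np.zeros((3, 3)))
        adj.iloc[0, 1] = adj.iloc[1, 0] = 0.0
        tom = tom_similarity(adj + np.eye(3))
        assert tom.iloc[0, 1] == 0.0
        assert np.allclose(np.diag(tom), 1.0)

    def test_complete_graph_all_one(self):
        # p=4, all a=1: TOM_ij = (2 + 1) / (3 + 1 - 1) = 1
        adj = pd.DataFrame(np.ones((4, 4)))
        tom = tom_similarity(adj)
        assert np.allclose(tom, 1.0)

    def test_hand_computed_triangle(self):
        a = np.array([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]])
        tom = tom_similarity(pd.DataFrame(a))
        # TOM_01 = (a02*a21 + a01) / (min(k0,k1)+1-a01); k0=0.7, k1=0.9
        expected = (0.2 * 0.4 + 0.5) / (0.7 + 1 - 0.5)
        assert tom.iloc[0, 1] == pytest.approx(expected)

    def test_out_of_range_adjacency_raises(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            tom_similarity(pd.DataFrame([[0, 2.0], [2.0, 0]]))


def modules_from_expr(expr, min_module_size=20, beta=6):
    cor = correlation_matrix(expr)
    adj, _ = adjacency_connectivity(cor, AdjacencyParams(beta=beta))
    return detect_modules(tom_similarity(adj), min_module_size=min_module_size)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr = block_expr(rng, [50, 50], loading=0.9, noise=0.45)
        labels = modules_from_expr(expr)
        non_grey = sorted(set(labels) - {GREY})
        assert len(non_grey) == 2
        # >= 95% agreement with the planted split
        truth = np.array([0] * 50 + [1] * 50)
        best = 0.0
        for flip in (False, True):
            mapping = dict(zip(non_grey, [1, 0] if flip else [0, 1]))
            agreement = np.mean([mapping.get(l, -1) == t
                                 for l, t in zip(labels, truth)])
            best = max(best, agreement)
        assert best >= 0.95

    def test_small_block_goes_grey(self, rng):
        expr = block_expr(rng, [5], loading=0.95, noise=0.1)
        with pytest.warns(UserWarning, match="all grey"):
            labels = modules_from_expr(expr, min_module_size=20)
        assert (labels == GREY).all()

    def test_deterministic(self, rng):
        expr = block_expr(rng, [30, 30], n=50)
        l1 = modules_from_expr(expr)
        l2 = modules_from_expr(expr)
        pd.testing.assert_series_equal(l1, l2)

    def test_labels_by_decreasing_size(self, rng):
        expr = block_expr(rng, [60, 25], loading=0.95, noise=0.3)
        labels = modules_from_expr(expr)
        sizes = labels[labels != GREY].value_counts()
        assert sizes.index[0] == "turquoise"
        assert sizes.iloc[0] >= sizes.iloc[-1]


class TestModuleEigengenes:
    def test_identical_genes_explain_everything(self, rng):
        base = rng.standard_normal(30)
        expr = expr_frame([base, 2 * base + 1, 0.5 * base])
        labels = pd.Series(["blue"] * 3, index=expr.index)
        eig, var = module_eigengenes(expr, labels)
        assert var["blue"] == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        assert abs(np.corrcoef(eig["blue"], z)[0, 1]) == pytest.approx(1.0)

    def test_orientation_positive_after_negation(self, rng):
        expr = block_expr(rng, [20], n=40)
        labels = pd.Series(["blue"] * 20, index=expr.index)
        eig_pos, _ = module_eigengenes(expr, labels)
        eig_neg, _ = module_eigengenes(-expr, labels)
        for eig, e in ((eig_pos, expr), (eig_neg, -expr)):
            cors = [np.corrcoef(e.loc[g], eig["blue"])[0, 1] for g in e.index]
            assert np.mean(cors) > 0

    def test_two_uncorrelated_halves_bounded_variance(self, rng):
        half1 = block_expr(rng, [20], loading=0.95, noise=0.1, n=60)
        half2 = block_expr(rng, [20], loading=0.95, noise=0.1, n=60)
        expr = pd.concat([half1, half2.set_index(half1.index + "_b")])
        labels = pd.Series(["blue"] * 40, index=expr.index)
        _, var = module_eigengenes(expr, labels)
        assert var["blue"] <= 0.75

    def test_singleton_module_raises(self, rng):
        expr = block_expr(rng, [3], n=10)
        labels = pd.Series(["blue", "red", "red"], index=expr.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengenes(expr, labels)


class TestMergeModules:
    def correlated_blocks(self, rng, r_pairs, size=20, n=80):
        """Blocks whose factors are correlated as requested pairwise to block 0."""
        f0 = rng.standard_normal(n)
        rows, labels = [], []
        for b, r in enumerate(r_pairs):
            f = r * f0 + np.sqrt(1 - r**2) * rng.standard_normal(n)
            rows.append(0.95 * f + 0.1 * rng.standard_normal((size, n)))
            labels += [f"mod{b}"] * size
        expr = expr_frame(np.vstack(rows))
        return expr, pd.Series(labels, index=expr.index, name="module")

    def test_high_correlation_merges(self, rng):
        expr, labels = self.correlated_blocks(rng, [1.0, 0.97])
        merged = merge_modules(labels, expr, r_min=0.9)
        assert len(set(merged)) == 1

    def test_low_correlation_does_not_merge(self, rng):
        expr, labels = self.correlated_blocks(rng, [1.0, 0.5])
        merged = merge_modules(labels, expr, r_min=0.9)
        assert set(merged) == {"mod0", "mod1"}

    def test_transitive_closure(self, rng):
        expr, labels = self.correlated_blocks(rng, [1.0, 0.96, 0.96])
        merged = merge_modules(labels, expr, r_min=0.9)
        assert len(set(merged)) == 1

    def test_grey_never_merges(self, rng):
        expr, labels = self.correlated_blocks(rng, [1.0, 0.99])
        labels.iloc[:20] = GREY
        merged = merge_modules(labels, expr, r_min=0.9)
        assert (merged.iloc[:20] == GREY).all()


class TestZsummaryBins:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (15.0, "HIGH"),
            (10.0, "WEAK_MODERATE"),  # boundary belongs to the middle bin
            (5.0, "WEAK_MODERATE"),
            (2.0, "WEAK_MODERATE"),
            (1.9, "NOT_PRESERVED"),
            (-4.0, "NOT_PRESERVED"),
        ],
    )
    def test_bins_partition_the_line(self, z, expected):
        assert zsummary_bin(z) == expected


class TestPreservationZsummary:
    def planted(self, rng, n=50):
        ref = block_expr(rng, [40, 160], loading=0.9, noise=0.4, n=n)
        labels = pd.Series([GREY] * 200, index=ref.index, name="module")
        labels.iloc[:40] = "blue"
        return ref, labels

    def test_self_preservation_of_random_set_is_null(self, rng):
        ref, _ = self.planted(rng)
        labels = pd.Series(GREY, index=ref.index, name="module")
        picks = rng.choice(len(ref), size=30, replace=False)
        labels.iloc[picks] = "blue"
        zs = [
            preservation_zsummary(ref, ref, labels, n_perm=60, seed=s)
            .loc["blue", "Zsummary"]
            for s in range(4)
        ]
        assert np.median(np.abs(zs)) < 3

    def test_invariant_to_sample_and_gene_order(self, rng):
        ref, labels = self.planted(rng, n=30)
        test = block_expr(rng, [40, 160], loading=0.9, noise=0.4, n=30)
        base = preservation_zsummary(ref, test, labels, n_perm=50, seed=1)
        perm_samples = list(rng.permutation(ref.columns))
        shuffled = preservation_zsummary(
            ref[perm_samples], test, labels, n_perm=50, seed=1
        )
        pd.testing.assert_frame_equal(base, shuffled)

    def test_stronger_loading_scores_higher(self, rng):
        medians = []
        for loading in (0.3, 0.9):
            zs = []
            for seed in range(3):
                r = np.random.default_rng(100 + seed)
                ref = block_expr(r, [40, 100], loading=loading, noise=0.5, n=40)
                test = block_expr(r, [40, 100], loading=loading, noise=0.5, n=40)
                labels = pd.Series([GREY] * 140, index=ref.index, name="module")
                labels.iloc[:40] = "blue"
                zs.append(
                    preservation_zsummary(ref, test, labels, n_perm=50, seed=seed)
                    .loc["blue", "Zsummary"]
                )
            medians.append(np.median(zs))
        assert medians[1] > medians[0]

    def test_invalid_n_perm_raises(self, rng):
        ref, labels = self.planted(rng, n=10)
        with pytest.raises(ValueError, match="n_perm"):
            preservation_zsummary(ref, ref, labels, n_perm=0)
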