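"""Student's t-test DE, consensus rule, rankings, marker filters."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from nksub import (RankedList, case_control_contrast_ranking, consensus_de,
                   cluster_contrast_ranking, de_between_clusters,
                   marker_genes, ttest_two_sample)
from nksub.qc_norm import ExprMatrix


def expr_matrix(dense, genes=None, sample_id="s1", group="case"):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(dense.shape[0])]
    cells = [f"c{j+1}" for j in range(dense.shape[1])]
    return ExprMatrix(genes, cells, sp.csr_matrix(dense), sample_id, group)


class TestTtest:
    def test_identical_groups(self):
        assert ttest_two_sample([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_hand_computed_pooled_t(self):
        """A=[1..4], B=[3..6]: pooled variance 5/3, t = -2/0.9129 = -2.1909."""
        t, p = ttest_two_sample([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.19089, abs=1e-4)
        assert p == pytest.approx(2 * stats.t.sf(2.19089, 6), abs=1e-4)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.standard_normal(rng.integers(2, 12))
            b = rng.standard_normal(rng.integers(2, 12))
            t, p = ttest_two_sample(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_conventions(self):
        assert ttest_two_sample([5, 5], [5, 5]) == (0.0, 1.0)
        t, p = ttest_two_sample([5, 5], [7, 7])
        assert t == -np.inf and p == 0.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.standard_normal(6), rng.standard_normal(9)
            t1, p1 = ttest_two_sample(a, b)
            t2, p2 = ttest_two_sample(b, a)
            assert t1 == pytest.approx(-t2, abs=1e-12)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_tiny_group_error(self):
        with pytest.raises(ValueError):
            ttest_two_sample([1], [2, 3])


class TestDeBetweenClusters:
    def test_excluded_genes_absent(self):
        rng = np.random.default_rng(0)
        e = expr_matrix(rng.uniform(0, 2, size=(5, 10)))
        labels = np.array([0, 1] * 5)
        de = de_between_clusters(e, labels, exclude_genes=["g2", "g4"])
        assert set(de["gene"]) == {"g1", "g3", "g5"}

    def test_mean_diff_sign_and_outlier_exclusion(self):
        dense = np.zeros((2, 8))
        dense[0, 4:] = 2.0          # g1 higher in cluster 1
        dense[1, 3] = 50.0          # huge value in an outlier cell
        e = expr_matrix(dense)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        flags = np.zeros(8, bool)
        flags[3] = True
        de = de_between_clusters(e, labels, outlier_flags=flags)
        row = de.set_index("gene").loc["g1"]
        assert row["mean_diff"] == pytest.approx(2.0)
        assert de.set_index("gene").loc["g2", "mean_diff"] == pytest.approx(0.0)

    def test_small_cluster_error(self):
        e = expr_matrix(np.random.default_rng(0).uniform(size=(3, 4)))
        with pytest.raises(ValueError):
            de_between_clusters(e, np.array([0, 0, 0, 1]))


def de_table(genes, ps, diffs):
    return pd.DataFrame({"gene": genes, "t": np.sign(diffs), "p": ps,
                         "p_adj": ps, "mean_diff": diffs})


class TestConsensusDe:
    def test_inclusion_rules(self):
        g = ["a", "b", "c"]
        t1 = de_table(g, [0.01, 0.01, 0.01], [1, 1, 1])
        t2 = de_table(g, [0.01, 0.20, 0.01], [1, 1, 1])
        t3 = de_table(g, [0.01, 0.01, 0.01], [1, 1, -1])
        # a: significant, same sign everywhere -> in
        # b: not significant in t2 -> out; c: sign flips in t3 -> out
        assert consensus_de([t1, t2, t3]) == ["a"]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        tables = [de_table(genes, rng.uniform(0, 0.2, 50),
                           rng.choice([-1.0, 1.0], 50)) for _ in range(3)]
        sizes = [len(consensus_de(tables, alpha=a))
                 for a in (0.01, 0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes)

    def test_disjoint_universes_error(self):
        t1 = de_table(["a"], [0.01], [1])
        t2 = de_table(["b"], [0.01], [1])
        with pytest.raises(ValueError):
            consensus_de([t1, t2])


def two_cluster_expr(contrast, n_per=4, sample_id="s", noise=0.0, seed=0):
    """Expression where cluster 1 cells sit at +contrast per gene."""
    rng = np.random.default_rng(seed)
    contrast = np.asarray(contrast, dtype=float)
    base = np.ones((len(contrast), 2 * n_per))
    base[:, n_per:] += contrast[:, None]
    base += noise * rng.standard_normal(base.shape)
    e = expr_matrix(np.abs(base), sample_id=sample_id)
    from nksub import subcluster_sample
    res = subcluster_sample(e, list(e.genes), seed=0)
    res.labels = np.array([0] * n_per + [1] * n_per)
    res.outlier_flags = np.zeros(2 * n_per, bool)
    return e, res


class TestRankings:
    def test_single_sample_contrast(self):
        e, r = two_cluster_expr([1.0, 0.0])
        rk = cluster_contrast_ranking([e], [r], ["g1", "g2"])
        assert rk.genes[0] == "g1"
        assert rk.scores[0] == pytest.approx(1.0)
        assert rk.scores[1] == pytest.approx(0.0)

    def test_opposite_contrasts_average_to_zero(self):
        e1, r1 = two_cluster_expr([1.0])
        e2, r2 = two_cluster_expr([-1.0])
        rk = cluster_contrast_ranking([e1, e2], [r1, r2], ["g1"])
        assert rk.scores[0] == pytest.approx(0.0)

    def test_sample_order_invariance(self):
        e1, r1 = two_cluster_expr([1.0, -0.5], noise=0.05, seed=1)
        e2, r2 = two_cluster_expr([0.5, 0.5], noise=0.05, seed=2)
        a = cluster_contrast_ranking([e1, e2], [r1, r2], ["g1", "g2"])
        b = cluster_contrast_ranking([e2, e1], [r2, r1], ["g1", "g2"])
        assert a.genes == b.genes
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_ties_broken_lexicographically(self):
        rl = RankedList(["b", "a", "c"], [1.0, 1.0, 2.0])
        assert rl.genes == ["c", "a", "b"]

    def test_delta_of_deltas_zero_when_groups_match(self):
        e1, r1 = two_cluster_expr([1.0, 2.0], sample_id="case1")
        e2, r2 = two_cluster_expr([1.0, 2.0], sample_id="ctrl1")
        rk = case_control_contrast_ranking([e1], [r1], [e2], [r2],
                                           ["g1", "g2"])
        np.testing.assert_allclose(rk.scores, 0.0, atol=1e-12)

    def test_amplified_case_effect_tops_ranking(self):
        e1, r1 = two_cluster_expr([2.0, 0.0], sample_id="case1")
        e2, r2 = two_cluster_expr([1.0, 0.0], sample_id="ctrl1")
        rk = case_control_contrast_ranking([e1], [r1], [e2], [r2],
                                           ["g1", "g2"])
        assert rk.genes[0] == "g1"
        assert rk.scores[0] == pytest.approx(1.0)

    def test_unknown_mode_error(self):
        e1, r1 = two_cluster_expr([1.0])
        with pytest.raises(ValueError, match="mode"):
            case_control_contrast_ranking([e1], [r1], [e1], [r1], ["g1"],
                                          mode="bogus")


class TestMarkerGenes:
    def test_min_pct_rule(self):
        dense = np.zeros((1, 20))
        dense[0, [0, 10]] = 1.0    # detected in 10% of each group
        e = expr_matrix(dense)
        labels = np.array([0] * 10 + [1] * 10)
        assert marker_genes(e, labels).empty

    def test_log2fc_strictly_above_threshold(self):
        """A gene whose |log2FC| does not exceed 0.25 is excluded."""
        mean_in = 2.0
        mean_out = (mean_in + 1) / 2 ** 0.2499 - 1
        dense = np.vstack([
            np.log1p(np.array([mean_in] * 5 + [mean_out] * 5)),
        ])
        e = expr_matrix(dense)
        labels = np.array([0] * 5 + [1] * 5)
        out = marker_genes(e, labels)
        assert out[out["group"] == 0].empty

    def test_strong_marker_included(self):
        dense = np.vstack([np.array([np.log(5.0)] * 5 + [np.log(1.25)] * 5)])
        e = expr_matrix(dense)
        labels = np.array(["hi"] * 5 + ["lo"] * 5)
        out = marker_genes(e, labels)
        hi = out[out["group"] == "hi"]
        assert list(hi["gene"]) == ["g1"]
        assert hi.iloc[0]["log2fc"] > 0.25

    def test_single_group_error(self):
        e = expr_matrix(np.ones((2, 4)))
        with pytest.raises(ValueError):
            marker_genes(e, np.zeros(4, dtype=int))
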