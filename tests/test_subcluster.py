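"""K-means subclustering: model selection, silhouette, outliers, harmonization."""

import itertools

import numpy as np
import pytest

from nksub import (flag_outliers, harmonize_cluster_labels, kmeans,
                   mean_silhouette, select_k, subcluster_sample)
from nksub.qc_norm import ExprMatrix

import scipy.sparse as sp


def brute_force_silhouette(points, labels):
    """O(n^2) silhouette straight from the definition."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            vals.append(0.0)
            continue
        a = dist[i, own].sum() / (own.sum() - 1)
        b = min(dist[i, labels == c].mean()
                for c in set(labels) if c != labels[i])
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def brute_force_kmeans_inertia(points, k):
    """Best inertia over all label assignments (tiny n only)."""
    points = np.asarray(points, dtype=float)
    best = np.inf
    for assign in itertools.product(range(k), repeat=len(points)):
        assign = np.array(assign)
        if len(set(assign)) < k:
            continue
        inertia = sum(
            ((points[assign == c] - points[assign == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
        best = min(best, inertia)
    return best


def blobs(centers, n_per, spread, seed=0):
    rng = np.random.default_rng(seed)
    return np.vstack([
        c + spread * rng.standard_normal((n_per, len(c)))
        for c in np.atleast_2d(centers)
    ])


class TestKmeans:
    def test_two_separated_pairs(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, centroids, inertia = kmeans(pts, 2, seed=0)
        assert labels[0] == labels[1] != labels[2]
        assert sorted(np.round(centroids.ravel(), 6)) == [0.05, 10.05]
        assert inertia == pytest.approx(0.01)

    def test_identical_points_zero_inertia(self):
        pts = np.ones((6, 2))
        labels, _, inertia = kmeans(pts, 2, seed=0)
        assert inertia == pytest.approx(0.0)
        assert len(labels) == 6

    def test_matches_exhaustive_assignment_oracle(self):
        """Lloyd's with restarts reaches the global optimum on tiny inputs."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 10, size=(7, 2))
            # many restarts so Lloyd's escapes local optima on tiny inputs
            _, _, inertia = kmeans(pts, 3, seed=0, n_init=100)
            assert inertia == pytest.approx(
                brute_force_kmeans_inertia(pts, 3), abs=1e-9)

    def test_inertia_nonincreasing_in_iterations(self):
        pts = blobs([[0, 0], [4, 4], [8, 0]], 20, 2.0, seed=1)
        from sklearn.cluster import KMeans
        inertias = [
            KMeans(n_clusters=3, n_init=1, init="random", random_state=0,
                   max_iter=it, tol=0.0).fit(pts).inertia_
            for it in range(1, 8)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_invalid_k(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError):
            kmeans(pts, 1, seed=0)
        with pytest.raises(ValueError):
            kmeans(pts, 5, seed=0)


class TestMeanSilhouette:
    def test_perfectly_separated(self):
        pts = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert mean_silhouette(pts, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_identical_points_zero(self):
        pts = np.ones((4, 1))
        assert mean_silhouette(pts, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        """1-D [0,1,5,6] split in the middle: mean silhouette 0.79798..."""
        pts = np.array([[0.0], [1.0], [5.0], [6.0]])
        got = mean_silhouette(pts, [0, 0, 1, 1])
        assert got == pytest.approx((4.5 / 5.5 + 3.5 / 4.5 + 3.5 / 4.5
                                     + 4.5 / 5.5) / 4, abs=1e-12)
        assert got == pytest.approx(0.7980, abs=1e-4)

    def test_single_cluster_is_error(self):
        with pytest.raises(ValueError):
            mean_silhouette(np.zeros((4, 1)), [0, 0, 0, 0])

    def test_agrees_with_brute_force_on_random_instances(self):
        """Matches the O(n^2) definitional oracle to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, 5))
            pts = rng.standard_normal((n, int(rng.integers(1, 4))))
            labels = rng.integers(0, k, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            assert mean_silhouette(pts, labels) == pytest.approx(
                brute_force_silhouette(pts, labels), abs=1e-12)


class TestSelectK:
    def test_recovers_two_blobs(self):
        pts = blobs([[0, 0], [10, 10]], 30, 0.5, seed=0)
        assert select_k(pts, seed=0).chosen_k == 2

    def test_recovers_three_blobs(self):
        pts = blobs([[0, 0], [10, 10], [20, 0]], 30, 0.5, seed=0)
        assert select_k(pts, seed=0).chosen_k == 3

    def test_deterministic_under_seed(self):
        pts = blobs([[0, 0], [6, 6]], 40, 1.5, seed=3)
        a = select_k(pts, seed=0)
        b = select_k(pts, seed=0)
        assert a.chosen_k == b.chosen_k
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.silhouette_by_k == b.silhouette_by_k

    def test_k_capped_at_n_minus_one(self, caplog):
        pts = blobs([[0], [10]], 3, 0.1, seed=0)   # 6 points
        with caplog.at_level("WARNING"):
            res = select_k(pts, k_min=2, k_max=10, seed=0)
        assert max(res.silhouette_by_k) == 5
        assert "capped" in caplog.text

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((2, 2)), k_min=2)


class TestFlagOutliers:
    def test_direct_arithmetic_example(self):
        """Nine 1's and one 20: cutoff 2.9 + 2*5.7 = 14.3, one flag."""
        d = np.array([1.0] * 9 + [20.0])
        flags = flag_outliers(d)
        assert flags.sum() == 1 and flags[-1]
        assert d.mean() == pytest.approx(2.9)
        assert d.std() == pytest.approx(5.7, abs=0.01)

    def test_constant_distances_no_flags(self):
        assert not flag_outliers(np.full(10, 3.0)).any()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.standard_normal(50))
        np.testing.assert_array_equal(flag_outliers(d), flag_outliers(7.3 * d))

    def test_half_normal_outlier_fraction_sane(self):
        """Under half-normal-ish distances, < 10% of cells are flagged."""
        for seed in range(10):
            d = np.abs(np.random.default_rng(seed).standard_normal(500))
            assert flag_outliers(d).mean() < 0.10

    def test_tiny_input_warns_no_flags(self, caplog):
        with caplog.at_level("WARNING"):
            flags = flag_outliers(np.array([1.0]))
        assert not flags.any()


def _expr_from_points(points, genes, sample_id):
    return ExprMatrix(genes=list(genes),
                      barcodes=[f"{sample_id}-{i}" for i in range(len(points))],
                      values=sp.csr_matrix(np.asarray(points).T),
                      sample_id=sample_id)


class TestHarmonize:
    def _make_sample(self, flip, sample_id, seed=0):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(seed)
        lo = rng.uniform(0.5, 0.7, size=(20, 6))
        # sign-varying effect (up on g0-g2, down on g3-g5), like real panels
        hi = lo + np.array([1.0, 1.0, 1.0, -0.5, -0.5, -0.5])
        pts = np.abs(np.vstack([lo, hi]))
        labels = np.array([0] * 20 + [1] * 20)
        if flip:
            labels = 1 - labels
        expr = _expr_from_points(pts, genes, sample_id)
        res = subcluster_sample(expr, genes, seed=0)
        # force the constructed coding
        res.labels = labels
        res.centroids = np.vstack([pts[labels == 0].mean(axis=0),
                                   pts[labels == 1].mean(axis=0)])
        return expr, res

    def test_swapped_coding_is_flipped(self):
        e1, r1 = self._make_sample(False, "s1")
        e2, r2 = self._make_sample(True, "s2", seed=1)
        out = harmonize_cluster_labels([r1, r2], [e1, e2])
        assert [r.orientation for r in out] == [1, -1]
        np.testing.assert_array_equal(out[0].labels, r1.labels)
        np.testing.assert_array_equal(out[1].labels, 1 - r2.labels)

    def test_single_sample_unchanged(self):
        e1, r1 = self._make_sample(False, "s1")
        out = harmonize_cluster_labels([r1], [e1])
        assert out[0].orientation == 1
        np.testing.assert_array_equal(out[0].labels, r1.labels)

    def test_orient_by_pins_cluster_one_to_up_genes(self):
        # coding where cluster 1 is the LOW block; orient_by must flip it
        e1, r1 = self._make_sample(True, "s1")
        unoriented = harmonize_cluster_labels([r1], [e1], orient_by=None)
        assert unoriented[0].labels[-1] == 0      # anchor coding kept
        out = harmonize_cluster_labels([r1], [e1], orient_by=["g0"])
        assert out[0].labels[-1] == 1             # hi block becomes cluster 1
        assert out[0].orientation == -1

    def test_non_two_cluster_sample_rejected(self):
        e1, r1 = self._make_sample(False, "s1")
        r1.chosen_k = 3
        with pytest.raises(ValueError, match="silhouette"):
            harmonize_cluster_labels([r1], [e1])

    def test_cohort_recovery(self, default_cohort):
        """Harmonized cluster 1 matches the planted subtype-1 NK state in
        every sample of the default cohort."""
        pc = default_cohort
        for res, sub in zip(pc.results, pc.truth_subtypes):
            ok = ~np.isnan(sub.astype(float))
            agree = (res.labels[ok] == sub[ok].astype(int)).mean()
            assert agree >= 0.9
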