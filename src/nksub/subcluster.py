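"""Panel-restricted K-means subclustering of NK cells.

Per sample: Lloyd's K-means (k-means++ init, n_init=10 keep-best,
random_state fixed for reproducibility) is run on the log-normalized NK
expression matrix restricted to a gene panel, candidate cluster numbers
k = 2..10 are scored by mean silhouette, the best k is chosen (ties toward
the smallest k), and cells lying more than 2 SD beyond the mean Euclidean
distance to their cluster centroid are flagged as outliers. Cluster
identities are then harmonized across samples by aligning per-sample
cluster-contrast vectors.

The feature space for clustering, silhouette, and centroid distances is the
unscaled log-normalized expression on panel ∩ matrix genes with the
Euclidean metric: no scaling or PCA is applied at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .qc_norm import ExprMatrix

log = logging.getLogger(__name__)

__all__ = ["SubclusterResult", "kmeans", "mean_silhouette", "select_k",
           "flag_outliers", "harmonize_cluster_labels", "subcluster_sample"]


@dataclass
class SubclusterResult:
    """Per-sample subclustering output."""

    sample_id: str
    panel_used: list[str]
    silhouette_by_k: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    centroids: np.ndarray
    distances: np.ndarray
    barcodes: list[str] = field(default_factory=list)
    outlier_flags: np.ndarray | None = None
    orientation: int = 1

    def included(self) -> np.ndarray:
        """Boolean mask of cells retained for downstream contrasts."""
        if self.outlier_flags is None:
            return np.ones(len(self.labels), dtype=bool)
        return ~self.outlier_flags


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means (k-means++ init, keep-best over ``n_init`` restarts).

    Returns (labels, centroids, inertia). Deterministic for a fixed seed;
    empty clusters are repaired internally by reseeding from high-cost
    points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D cell x feature array")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {points.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed)
    labels = km.fit_predict(points)
    return labels, km.cluster_centers_, float(km.inertia_)


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) over all points.

    a is the mean intra-cluster distance excluding self; b the minimum over
    other clusters of the mean distance. Cells in singleton clusters and
    cells where a = b = 0 score 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if np.all(counts == 1):
        return 0.0
    vals = silhouette_samples(points, labels)
    # sklearn leaves NaN for degenerate (all-identical) configurations.
    return float(np.nan_to_num(vals, nan=0.0).mean())


def select_k(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    sample_id: str = "sample",
    panel_used: list[str] | None = None,
    barcodes: list[str] | None = None,
) -> SubclusterResult:
    """Choose k in [k_min, k_max] by maximal mean silhouette.

    Runs K-means for every candidate k (capped at n-1 with a warning),
    computes the mean silhouette, and keeps the argmax; ties break toward
    the smallest k. Distances are Euclidean to the own-cluster centroid.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if n < k_min + 1:
        raise ValueError(f"need at least {k_min + 1} points, have {n}")
    k_hi = min(k_max, n - 1)
    if k_hi < k_max:
        log.warning("%s: k_max capped at %d (only %d points)", sample_id, k_hi, n)

    fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    sils: dict[int, float] = {}
    for k in range(k_min, k_hi + 1):
        labels, centroids, _ = kmeans(points, k, seed=seed)
        fits[k] = (labels, centroids)
        sils[k] = mean_silhouette(points, labels)
    chosen_k = max(sils, key=lambda k: (sils[k], -k))
    labels, centroids = fits[chosen_k]
    distances = np.linalg.norm(points - centroids[labels], axis=1)
    return SubclusterResult(
        sample_id=sample_id,
        panel_used=list(panel_used) if panel_used is not None else [],
        silhouette_by_k=sils,
        chosen_k=chosen_k,
        labels=labels.copy(),
        centroids=centroids.copy(),
        distances=distances,
        barcodes=list(barcodes) if barcodes is not None else [],
    )


def flag_outliers(distances: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Flag cells with distance > mean + n_sd * SD of all pooled distances.

    SD uses the population (n) denominator over all cells pooled; the
    inequality is strict, so a zero-spread vector yields no flags.
    """
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0) or not np.all(np.isfinite(distances)):
        raise ValueError("distances must be nonnegative and finite")
    if distances.size < 2:
        log.warning("fewer than 2 cells; no outlier flags assigned")
        return np.zeros(distances.size, dtype=bool)
    cutoff = distances.mean() + n_sd * distances.std()
    return distances > cutoff


def subcluster_sample(
    expr: ExprMatrix,
    panel: list[str],
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_sd: float = 2.0,
) -> SubclusterResult:
    """Convenience wrapper: panel-restrict, select k, flag outliers."""
    panel_used = [g for g in panel if g in set(expr.genes)]
    if not panel_used:
        raise ValueError("panel does not intersect the matrix gene axis")
    points = expr.dense_submatrix(panel_used)
    res = select_k(points, k_min=k_min, k_max=k_max, seed=seed,
                   sample_id=expr.sample_id, panel_used=panel_used,
                   barcodes=expr.barcodes)
    res.outlier_flags = flag_outliers(res.distances, n_sd=n_sd)
    return res


def _contrast_vector(
    expr: ExprMatrix, result: SubclusterResult, genes: list[str],
    exclude_outliers: bool = True,
) -> np.ndarray:
    X = expr.dense_submatrix(genes)  # cells x genes
    keep = result.included() if exclude_outliers else np.ones(len(result.labels), bool)
    m1 = X[(result.labels == 1) & keep].mean(axis=0)
    m0 = X[(result.labels == 0) & keep].mean(axis=0)
    return m1 - m0


def harmonize_cluster_labels(
    results: list[SubclusterResult],
    exprs: list[ExprMatrix],
    exclude_outliers: bool = True,
    orient_by: list[str] | None = None,
) -> list[SubclusterResult]:
    """Give cluster labels 0/1 a consistent meaning across samples.

    Every sample must have chosen_k = 2. Per sample the contrast vector
    d_s = mean(cluster 1) - mean(cluster 0) over the shared panel genes is
    computed; the first sample anchors the coding and any other sample whose
    contrast correlates negatively (Pearson) with the anchor's is flipped
    (orientation -1). After alignment all pairwise contrast correlations are
    nonnegative.

    The anchor's own coding is arbitrary (K-means labels carry no meaning).
    If ``orient_by`` is given, a final global flip makes the mean harmonized
    contrast over those genes nonnegative, pinning cluster 1 to the state in
    which they are up-regulated.
    """
    if len(results) != len(exprs):
        raise ValueError("results and expression matrices must match 1:1")
    for r in results:
        if r.chosen_k != 2:
            raise ValueError(
                f"{r.sample_id}: chosen_k={r.chosen_k}, harmonization needs "
                "k=2 in every sample; inspect the silhouette-vs-k curves"
            )
    shared = set(results[0].panel_used)
    for r in results[1:]:
        shared &= set(r.panel_used)
    genes = [g for g in results[0].panel_used if g in shared]
    if not genes:
        raise ValueError("no shared panel genes across samples")

    contrasts = [
        _contrast_vector(e, r, genes, exclude_outliers)
        for r, e in zip(results, exprs)
    ]
    anchor = contrasts[0]
    out: list[SubclusterResult] = []
    flips: list[int] = []
    for r, d in zip(results, contrasts):
        if d is anchor:
            flip = 1
        else:
            sd_a, sd_d = anchor.std(), d.std()
            if sd_a == 0 or sd_d == 0:
                log.warning("%s: degenerate contrast vector; not flipped",
                            r.sample_id)
                flip = 1
            else:
                corr = float(np.corrcoef(anchor, d)[0, 1])
                flip = 1 if corr >= 0 else -1
        flips.append(flip)

    if orient_by is not None:
        og = [g for g in orient_by if g in set(genes)]
        if og:
            pos = [genes.index(g) for g in og]
            mean_contrast = float(
                np.mean([f * d[pos].mean() for f, d in zip(flips, contrasts)])
            )
            if mean_contrast < 0:
                flips = [-f for f in flips]

    for r, flip in zip(results, flips):
        if flip == 1:
            out.append(replace(r, orientation=1))
        else:
            out.append(
                replace(
                    r,
                    labels=1 - r.labels,
                    centroids=r.centroids[::-1].copy(),
                    orientation=-1,
                )
            )
    return out
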