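"""Differential expression between harmonized NK clusters and ranked lists.

Per sample, every gene not used for clustering is tested with a pooled-
variance two-sample, two-tailed Student's t-test on log-normalized values.
A consensus list keeps genes significant with a consistent direction in
every required sample. Ranked lists for enrichment analysis score each gene
by the cluster-1 minus cluster-0 mean difference averaged across samples,
or by a case-minus-control contrast of those differences.

No multiple-testing correction is applied inside the per-gene test (the
consensus rule and the permutation-based enrichment FDR are the downstream
controls); a BH-adjusted column is emitted for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc_norm import ExprMatrix
from .subcluster import SubclusterResult

log = logging.getLogger(__name__)

__all__ = ["RankedList", "ttest_two_sample", "de_between_clusters",
           "consensus_de", "cluster_contrast_ranking",
           "case_control_contrast_ranking", "marker_genes"]


@dataclass
class RankedList:
    """Genes with scores, strictly ordered: descending score, ties broken
    lexicographically by symbol."""

    genes: list[str]
    scores: np.ndarray
    universe: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list genes must be unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranked list scores must be finite")
        order = sorted(range(len(self.genes)),
                       key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})

    def write_rnk(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def _ttest_arrays(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance Student's t over columns of cell x gene arrays.

    Degenerate convention: zero pooled variance gives (0, 1) for equal means
    and (signed inf, 0) otherwise.
    """
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 values")
    df = nA + nB - 2
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    vA = A.var(axis=0, ddof=1)
    vB = B.var(axis=0, ddof=1)
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / df
    se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    diff = mA - mB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = sp2 == 0
    eq = zero_var & (diff == 0)
    ne = zero_var & (diff != 0)
    t = np.where(eq, 0.0, t)
    p = np.where(eq, 1.0, p)
    t = np.where(ne, np.sign(diff) * np.inf, t)
    p = np.where(ne, 0.0, p)
    return t, p


def ttest_two_sample(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample, two-tailed Student's t-test.

    df = nA + nB - 2; p comes from the t distribution. Both groups need at
    least 2 values.
    """
    a = np.asarray(group_a, dtype=float)[:, None]
    b = np.asarray(group_b, dtype=float)[:, None]
    t, p = _ttest_arrays(a, b)
    return float(t[0]), float(p[0])


def de_between_clusters(
    expr: ExprMatrix,
    labels: np.ndarray,
    exclude_genes=(),
    outlier_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Test every gene not in ``exclude_genes`` between clusters 1 and 0.

    ``labels`` are harmonized 2-cluster labels over the matrix's cells;
    flagged outliers are dropped before testing. Returns per gene the t
    statistic, two-tailed p, BH-adjusted p, and the cluster1 - cluster0 mean
    difference in natural-log units.
    """
    labels = np.asarray(labels)
    keep = np.ones(len(labels), dtype=bool)
    if outlier_flags is not None:
        keep &= ~np.asarray(outlier_flags, dtype=bool)
    excl = set(exclude_genes)
    genes = [g for g in expr.genes if g not in excl]
    if not genes:
        raise ValueError("no genes left to test after exclusion")
    X = expr.dense_submatrix(genes)
    in1 = keep & (labels == 1)
    in0 = keep & (labels == 0)
    if in1.sum() < 2 or in0.sum() < 2:
        raise ValueError("each cluster needs at least 2 non-outlier cells")
    t, p = _ttest_arrays(X[in1], X[in0])
    mean_diff = X[in1].mean(axis=0) - X[in0].mean(axis=0)
    return pd.DataFrame(
        {
            "gene": genes,
            "t": t,
            "p": p,
            "p_adj": stats.false_discovery_control(np.clip(p, 0, 1)),
            "mean_diff": mean_diff,
        }
    )


def consensus_de(
    tables: list[pd.DataFrame],
    alpha: float = 0.05,
    samples_required: str | int = "all",
) -> list[str]:
    """Genes significant (p < alpha) with identical direction in every
    required sample.

    With ``samples_required="all"`` (default) a gene must pass in every
    table; an integer requires at least that many significant tables, with
    all significant ones agreeing in sign.
    """
    if not tables:
        raise ValueError("at least one DE table required")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    universe = set(tables[0]["gene"])
    for t in tables[1:]:
        universe &= set(t["gene"])
    if not universe:
        raise ValueError("DE tables share no genes")
    indexed = [t.set_index("gene") for t in tables]
    ordered = [g for g in tables[0]["gene"] if g in universe]
    out = []
    need = len(tables) if samples_required == "all" else int(samples_required)
    for g in ordered:
        ps = np.array([t.loc[g, "p"] for t in indexed])
        ds = np.array([t.loc[g, "mean_diff"] for t in indexed])
        sig = ps < alpha
        if sig.sum() < need:
            continue
        signs = np.sign(ds[sig] if samples_required != "all" else ds)
        if np.all(signs > 0) or np.all(signs < 0):
            out.append(g)
    return out


def _sample_contrasts(
    exprs: list[ExprMatrix],
    results: list[SubclusterResult],
    genes: list[str],
    exclude_outliers: bool = True,
) -> np.ndarray:
    rows = []
    for e, r in zip(exprs, results):
        X = e.dense_submatrix(genes)
        keep = r.included() if exclude_outliers else np.ones(len(r.labels), bool)
        rows.append(X[(r.labels == 1) & keep].mean(axis=0)
                    - X[(r.labels == 0) & keep].mean(axis=0))
    return np.vstack(rows)  # samples x genes


def cluster_contrast_ranking(
    exprs: list[ExprMatrix],
    results: list[SubclusterResult],
    universe: list[str],
    exclude_outliers: bool = True,
    tag: str = "",
) -> RankedList:
    """Rank genes by the cluster-1 minus cluster-0 mean difference averaged
    across samples (invariant to sample order)."""
    if not exprs:
        raise ValueError("at least one sample required")
    shared = set(universe)
    for e in exprs:
        shared &= set(e.genes)
    genes = [g for g in universe if g in shared]
    if not genes:
        raise ValueError("universe does not intersect the matrix genes")
    contrasts = _sample_contrasts(exprs, results, genes, exclude_outliers)
    return RankedList(genes=genes, scores=contrasts.mean(axis=0),
                      universe=tag or f"{len(genes)} genes")


def case_control_contrast_ranking(
    case_exprs: list[ExprMatrix],
    case_results: list[SubclusterResult],
    control_exprs: list[ExprMatrix],
    control_results: list[SubclusterResult],
    universe: list[str],
    mode: str = "delta_of_deltas",
    exclude_outliers: bool = True,
    tag: str = "",
) -> RankedList:
    """Rank genes by a case-minus-control contrast of cluster signatures.

    ``delta_of_deltas`` (default): mean case cluster contrast minus mean
    control cluster contrast. ``cluster1_profile``: mean cluster-1
    expression across cases minus across controls. The mode is recorded in
    the universe tag.
    """
    if mode not in ("delta_of_deltas", "cluster1_profile"):
        raise ValueError(f"unknown mode {mode!r}")
    if not case_exprs or not control_exprs:
        raise ValueError("both groups need at least one sample")
    shared = set(universe)
    for e in (*case_exprs, *control_exprs):
        shared &= set(e.genes)
    genes = [g for g in universe if g in shared]
    if not genes:
        raise ValueError("universe does not intersect the matrix genes")
    if mode == "delta_of_deltas":
        case = _sample_contrasts(case_exprs, case_results, genes,
                                 exclude_outliers).mean(axis=0)
        ctrl = _sample_contrasts(control_exprs, control_results, genes,
                                 exclude_outliers).mean(axis=0)
        scores = case - ctrl
    else:
        def cluster1_mean(exprs, results):
            rows = []
            for e, r in zip(exprs, results):
                X = e.dense_submatrix(genes)
                keep = (r.included() if exclude_outliers
                        else np.ones(len(r.labels), bool))
                rows.append(X[(r.labels == 1) & keep].mean(axis=0))
            return np.vstack(rows).mean(axis=0)

        scores = (cluster1_mean(case_exprs, case_results)
                  - cluster1_mean(control_exprs, control_results))
    return RankedList(genes=genes, scores=scores,
                      universe=f"{tag or 'case_vs_control'}|mode={mode}")


def marker_genes(
    expr: ExprMatrix,
    labels: np.ndarray,
    min_pct: float = 0.25,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Marker genes per group (one-vs-rest) under min.pct and log2FC filters.

    A gene is a marker for a group if it is detected (count > 0) in at least
    ``min_pct`` of cells in the group or in the rest, and the absolute log2
    fold change of group means — computed on expm1-backtransformed
    normalized expression with pseudocount 1 — strictly exceeds
    ``min_abs_log2fc``.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    X = expr.dense_submatrix(list(expr.genes))  # cells x genes
    rows = []
    for grp in groups:
        sel = labels == grp
        if sel.sum() == 0 or (~sel).sum() == 0:
            raise ValueError(f"group {grp!r} or its complement is empty")
        pct_in = (X[sel] > 0).mean(axis=0)
        pct_out = (X[~sel] > 0).mean(axis=0)
        mean_in = np.expm1(X[sel]).mean(axis=0)
        mean_out = np.expm1(X[~sel]).mean(axis=0)
        log2fc = np.log2(mean_in + 1) - np.log2(mean_out + 1)
        keep = (np.maximum(pct_in, pct_out) >= min_pct) & \
               (np.abs(log2fc) > min_abs_log2fc)
        for j in np.flatnonzero(keep):
            rows.append({"group": grp, "gene": expr.genes[j],
                         "pct_in": pct_in[j], "pct_out": pct_out[j],
                         "log2fc": log2fc[j]})
    return pd.DataFrame(rows, columns=["group", "gene", "pct_in", "pct_out",
                                       "log2fc"])
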