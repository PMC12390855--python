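"""Cell-type assignment by Spearman correlation to reference profiles.

Each cell is correlated (Spearman, average ranks for ties) against per-type
mean log-normalized expression profiles over a marker gene list, and
assigned the argmax type. This is a deliberately simple single-round
annotator: no iterative fine-tuning, no per-reference-cell quantile
aggregation, no score pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .qc_norm import ExprMatrix

log = logging.getLogger(__name__)

__all__ = ["ReferenceProfiles", "build_reference", "assign_cell_types",
           "extract_cell_type", "read_reference_tsv", "write_reference_tsv"]

MIN_SHARED_GENES = 10


@dataclass
class ReferenceProfiles:
    """Per-type mean log-normalized expression over a shared gene list."""

    genes: list[str]
    types: list[str]
    values: np.ndarray  # genes x types

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.types) < 2:
            raise ValueError("reference needs at least 2 cell types")
        if self.values.shape != (len(self.genes), len(self.types)):
            raise ValueError("profile matrix shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference profiles must be finite")

    def default_markers(self, n_top: int = 50) -> list[str]:
        """Union over types of each type's top ``n_top`` one-vs-rest genes.

        Per type, genes are ranked by the profile's excess over the mean of
        the other types' profiles, so every type contributes markers even
        when overall variance is dominated by a few highly expressed genes.
        """
        chosen: set[int] = set()
        for t in range(len(self.types)):
            others = np.delete(self.values, t, axis=1).mean(axis=1)
            excess = self.values[:, t] - others
            chosen.update(np.argsort(-excess, kind="stable")[:n_top].tolist())
        return [self.genes[i] for i in sorted(chosen)]


def build_reference(expr: ExprMatrix, labels) -> ReferenceProfiles:
    """Average log-normalized expression per labeled type (each type >=2 cells)."""
    labels = np.asarray(labels)
    if labels.shape[0] != expr.n_cells:
        raise ValueError("one label per cell required")
    types = sorted(set(labels))
    cols = []
    for t in types:
        sel = np.flatnonzero(labels == t)
        if len(sel) < 2:
            raise ValueError(f"type {t!r} has fewer than 2 cells")
        cols.append(np.asarray(expr.values[:, sel].mean(axis=1)).ravel())
    return ReferenceProfiles(genes=list(expr.genes), types=types,
                             values=np.column_stack(cols))


def assign_cell_types(
    expr: ExprMatrix,
    ref: ReferenceProfiles,
    marker_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each cell the reference type with the highest Spearman correlation.

    Correlations are computed over ``marker_genes`` intersected with the
    matrix and reference gene lists (default: the reference's top-50
    variance genes). Cells constant across the scored genes get the label
    "unassigned" with score NaN; argmax ties go to the earlier reference
    type with a logged warning.
    """
    if marker_genes is None:
        marker_genes = ref.default_markers()
    ref_idx = {g: i for i, g in enumerate(ref.genes)}
    expr_idx = expr.gene_index()
    shared = [g for g in marker_genes if g in ref_idx and g in expr_idx]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} shared genes between matrix and reference; "
            f"need >= {MIN_SHARED_GENES}"
        )
    X = expr.dense_submatrix(shared)              # cells x genes
    P = ref.values[[ref_idx[g] for g in shared]]  # genes x types

    cell_ranks = rankdata(X, axis=1)
    prof_ranks = rankdata(P.T, axis=1)            # types x genes
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    pr = prof_ranks - prof_ranks.mean(axis=1, keepdims=True)
    cell_sd = np.sqrt((cr ** 2).sum(axis=1))
    prof_sd = np.sqrt((pr ** 2).sum(axis=1))
    constant_cells = cell_sd == 0
    if np.any(prof_sd == 0):
        raise ValueError("a reference profile is constant over the marker genes")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cr @ pr.T) / np.outer(np.where(cell_sd > 0, cell_sd, 1.0), prof_sd)

    best = np.argmax(corr, axis=1)
    n_tied = int(np.sum((corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_tied:
        log.warning("%d cells had tied correlations; earliest reference type kept",
                    n_tied)
    labels = np.array(ref.types, dtype=object)[best]
    scores = corr[np.arange(corr.shape[0]), best]
    labels[constant_cells] = "unassigned"
    scores = np.where(constant_cells, np.nan, scores)
    return pd.DataFrame(
        {"label": labels, "score": scores},
        index=pd.Index(expr.barcodes, name="barcode"),
    )


def extract_cell_type(expr: ExprMatrix, labels, target: str = "NK") -> ExprMatrix:
    """Column-subset the matrix to cells labeled ``target`` (order preserved)."""
    labels = np.asarray(labels)
    mask = labels == target
    if not mask.any():
        raise ValueError(f"no cells labeled {target!r}")
    log.info("%s: extracted %d/%d %s cells", expr.sample_id, mask.sum(),
             len(mask), target)
    return expr.subset_cells(mask)


def write_reference_tsv(ref: ReferenceProfiles, path: str | Path) -> None:
    df = pd.DataFrame(ref.values, index=pd.Index(ref.genes, name="gene"),
                      columns=ref.types)
    df.to_csv(path, sep="\t")


def read_reference_tsv(path: str | Path) -> ReferenceProfiles:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReferenceProfiles(genes=list(df.index), types=list(df.columns),
                             values=df.to_numpy())
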