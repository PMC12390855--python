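"""Cell-level quality control and log-normalization.

Cells are retained if they have more than ``min_genes`` and fewer than
``max_genes`` detected genes and a mitochondrial read fraction strictly
below ``max_mito`` (defaults 200 / 5,000 / 0.15; all three boundaries are
strict). Expression is normalized per cell to ``scale`` total counts (default
10,000) and transformed with the natural log of (1 + value) — the
LogNormalize convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import CountMatrix

log = logging.getLogger(__name__)

__all__ = ["ExprMatrix", "FilterResult", "compute_cell_qc", "filter_cells",
           "log_normalize"]


@dataclass
class ExprMatrix:
    """Log-normalized real-valued gene x cell matrix (zeros implicit)."""

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix
    sample_id: str = "sample"
    group: str = "control"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def dense_submatrix(self, genes: list[str]) -> np.ndarray:
        """Dense cell x gene array restricted to ``genes`` (in that order)."""
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return np.asarray(self.values[rows, :].todense()).T

    def subset_cells(self, mask: np.ndarray) -> "ExprMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return ExprMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in cols],
            values=self.values[:, cols].tocsr(),
            sample_id=self.sample_id,
            group=self.group,
        )


def compute_cell_qc(matrix: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC statistics: genes_detected, total_counts, mito_fraction.

    Mitochondrial genes are identified by symbol prefix. Cells with zero
    total counts get mito_fraction 0 by convention.
    """
    X = matrix.values.tocsc()
    genes_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in matrix.genes])
    if not mito_mask.any():
        log.warning("no genes with prefix %r in universe; mito_fraction set to 0",
                    mito_prefix)
        mito_counts = np.zeros_like(total)
    else:
        mito_counts = np.asarray(X[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_counts": total.astype(int),
            "mito_fraction": mito_fraction,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


@dataclass
class FilterResult:
    matrix: CountMatrix
    retained_barcodes: list[str]
    tallies: dict[str, int]
    rejected: dict[str, list[str]]


def filter_cells(
    matrix: CountMatrix,
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.15,
) -> FilterResult:
    """Retain cells with min_genes < genes_detected < max_genes and
    mito_fraction < max_mito (all strict).

    ``qc`` must come from :func:`compute_cell_qc` on the same matrix. The
    gene axis is unchanged. Per-rule rejection tallies count each rule
    independently (a cell violating two rules appears in both).
    """
    if list(qc.index) != list(matrix.barcodes):
        raise ValueError("QC table was not computed from this matrix")
    gd = qc["genes_detected"].to_numpy()
    mf = qc["mito_fraction"].to_numpy()
    low = gd <= min_genes
    high = gd >= max_genes
    mito = mf >= max_mito
    keep = ~(low | high | mito)
    if not keep.any():
        raise ValueError("no cells survive QC filtering")
    barcodes = np.array(matrix.barcodes)
    retained = matrix.values[:, keep].tocsr()
    out = CountMatrix(
        genes=list(matrix.genes),
        barcodes=list(barcodes[keep]),
        values=retained,
        sample_id=matrix.sample_id,
        group=matrix.group,
    )
    tallies = {"low_genes": int(low.sum()), "high_genes": int(high.sum()),
               "high_mito": int(mito.sum())}
    rejected = {"low_genes": list(barcodes[low]), "high_genes": list(barcodes[high]),
                "high_mito": list(barcodes[mito])}
    log.info(
        "%s: retained %d/%d cells (rejected low=%d high=%d mito=%d)",
        matrix.sample_id, keep.sum(), len(keep),
        tallies["low_genes"], tallies["high_genes"], tallies["high_mito"],
    )
    return FilterResult(out, list(barcodes[keep]), tallies, rejected)


def log_normalize(matrix: CountMatrix, scale: float = 10000.0) -> ExprMatrix:
    """LogNormalize: value(g, c) = ln(1 + scale * count(g, c) / total(c)).

    The sparsity pattern is preserved (zero counts map to zero values).
    Cells with zero total counts are an error — filter first.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    X = matrix.values.tocsc().astype(np.float64)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total counts present; run filter_cells first"
        )
    X = X @ sp.diags(scale / totals)
    X.data = np.log1p(X.data)
    return ExprMatrix(
        genes=list(matrix.genes),
        barcodes=list(matrix.barcodes),
        values=X.tocsr(),
        sample_id=matrix.sample_id,
        group=matrix.group,
    )
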