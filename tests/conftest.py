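"""Shared fixtures: synthetic cohorts processed through the pipeline stages.

The session-scoped default cohort mirrors the package's documented study
conditions (6 samples, planted two-subtype NK compartment, seed 0) and is
shared by the subclustering, enrichment and acceptance tests to keep the
suite fast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pytest

from nksub import (
    ExprMatrix,
    SimConfig,
    SubclusterResult,
    assign_cell_types,
    build_reference,
    compute_cell_qc,
    default_config,
    extract_cell_type,
    filter_cells,
    generate_cohort,
    harmonize_cluster_labels,
    log_normalize,
    subcluster_sample,
)


def small_config(seed: int = 0, base_effect: float = 1.0,
                 cells: int = 500, n_genes: int = 300,
                 n_case: int = 3, n_control: int = 0) -> SimConfig:
    """A scaled-down cohort for fast module-level tests."""
    regular = [f"G{i:04d}" for i in range(1, n_genes - 13 + 1)]
    return replace(
        default_config(),
        n_samples_case=n_case,
        n_samples_control=n_control,
        cells_per_sample=cells,
        n_genes=n_genes,
        base_effect=base_effect,
        cell_type_proportions={"NK": 0.4, "T": 0.3, "B": 0.15, "Mono": 0.15},
        up_panel=tuple(regular[:60]),
        down_panel=tuple(regular[60:120]),
        null_panel=tuple(regular[120:]),
        seed=seed,
    )


@dataclass
class ProcessedCohort:
    config: SimConfig
    nk_exprs: list[ExprMatrix]
    results: list[SubclusterResult]
    truth_subtypes: list[np.ndarray]
    sample_groups: list[str]


def process_cohort(cfg: SimConfig, annotate_with_truth_reference: bool = True,
                   harmonize: bool = True) -> ProcessedCohort:
    """QC -> normalize -> annotate -> extract NK -> subcluster -> harmonize.

    The cell-type reference is built from the first sample's truth-labeled
    cells, the same closed loop the acceptance recomputation uses.
    """
    mats, truth = generate_cohort(cfg)
    exprs, results, subtypes, groups = [], [], [], []
    reference = None
    for m in mats:
        filt = filter_cells(m, compute_cell_qc(m))
        expr = log_normalize(filt.matrix)
        true_types = (
            truth.cells[truth.cells["sample_id"] == m.sample_id]
            .set_index("barcode")["cell_type"]
            .loc[expr.barcodes]
            .to_numpy()
        )
        if annotate_with_truth_reference:
            if reference is None:
                reference = build_reference(expr, true_types)
            labels = assign_cell_types(expr, reference)["label"].to_numpy()
        else:
            labels = true_types
        nk = extract_cell_type(expr, labels, "NK")
        res = subcluster_sample(nk, cfg.clustering_panel, seed=0)
        exprs.append(nk)
        results.append(res)
        subtypes.append(
            truth.nk_subtypes(m.sample_id).reindex(nk.barcodes).to_numpy()
        )
        groups.append(m.group)
    if harmonize and all(r.chosen_k == 2 for r in results):
        results = harmonize_cluster_labels(results, exprs,
                                           orient_by=list(cfg.up_panel))
    return ProcessedCohort(cfg, exprs, results, subtypes, groups)


@pytest.fixture(scope="session")
def default_cohort() -> ProcessedCohort:
    """The default 6-sample cohort, processed end to end once per session."""
    return process_cohort(default_config())


@pytest.fixture(scope="session")
def small_cohort() -> ProcessedCohort:
    """A fast 3-sample case-only cohort with truth-based NK extraction."""
    return process_cohort(small_config(), annotate_with_truth_reference=False)
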