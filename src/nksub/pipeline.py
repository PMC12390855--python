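"""End-to-end orchestration: ingest -> QC -> normalize -> annotate ->
subcluster -> harmonize -> DE -> GSEA, with a config file and fixed seeds.

Outputs per sample: a QC table, a cluster/outlier assignment TSV, and a
silhouette-vs-k TSV. Cohort level: the consensus DE list, ranked lists for
the cluster contrast on the clustering panel and on the non-panel consensus
genes, case-vs-control ranked lists, the four corresponding GSEA tables, and
a machine-readable run manifest. Reruns with an identical config produce
byte-identical result tables.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import assign_cell_types, extract_cell_type, read_reference_tsv
from .diffexp import (RankedList, case_control_contrast_ranking, consensus_de,
                      cluster_contrast_ranking, de_between_clusters)
from .gsea import gsea_preranked
from .matrix_io import (read_10x_mtx, read_gene_panel, read_gmt,
                        read_samples_manifest)
from .qc_norm import compute_cell_qc, filter_cells, log_normalize
from .subcluster import harmonize_cluster_labels, subcluster_sample

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

_GSEA_COLUMNS = ["set", "size", "es", "nes", "p", "q", "leading_edge"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and sample for context."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


@dataclass
class PipelineConfig:
    """All knobs of a run. Defaults follow the analysis protocol the package
    implements: QC at 200/5,000 detected genes and 15% mito reads, scale
    10,000, k = 2-10 with clustering seed 0, 2-SD outlier rule, alpha 0.05."""

    samples_manifest: str | None = None
    gene_panel: str | None = None
    gene_sets: str | None = None
    reference_profiles: str | None = None
    orientation_signature: str | None = None
    output_dir: str = "nksub_run"
    min_genes: int = 200
    max_genes: int = 5000
    max_mito: float = 0.15
    mito_prefix: str = "MT-"
    scale: float = 10000.0
    k_min: int = 2
    k_max: int = 10
    clustering_seed: int = 0
    outlier_n_sd: float = 2.0
    exclude_outliers: bool = True
    de_alpha: float = 0.05
    consensus_samples: str = "all"
    case_control_mode: str = "delta_of_deltas"
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_weight: float = 1.0
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0 < self.max_mito <= 1):
            raise ValueError("max_mito must lie in (0, 1]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.outlier_n_sd <= 0:
            raise ValueError("outlier_n_sd must be positive")
        if not (0 < self.de_alpha < 1):
            raise ValueError("de_alpha must lie in (0, 1)")
        if self.gsea_n_perm < 1:
            raise ValueError("gsea_n_perm must be >= 1")
        if self.gsea_min_size < 1 or self.gsea_max_size < self.gsea_min_size:
            raise ValueError("gsea sizes must satisfy 1 <= min <= max")
        if self.case_control_mode not in ("delta_of_deltas", "cluster1_profile"):
            raise ValueError("unknown case_control_mode")
        for key in ("samples_manifest", "gene_panel", "gene_sets",
                    "reference_profiles", "orientation_signature"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: no such path: {val}")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML/JSON config file, fill defaults, and validate ranges.

    Unknown keys are an error (listed); out-of-range values report the
    documented range. An empty file yields the full-default configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw).validate()


def _write_gsea(ranked: RankedList | None, collection, cfg: PipelineConfig,
                path: Path, seed: int) -> None:
    """Run GSEA if the ranked list is usable, else emit a header-only table."""
    if ranked is not None and len(ranked) >= 2 * cfg.gsea_min_size:
        try:
            table = gsea_preranked(
                ranked, collection, n_perm=cfg.gsea_n_perm, seed=seed,
                min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size,
                weight_p=cfg.gsea_weight,
            )
        except ValueError as exc:
            log.warning("%s: %s; writing empty table", path.name, exc)
            table = pd.DataFrame(columns=_GSEA_COLUMNS)
    else:
        n = 0 if ranked is None else len(ranked)
        log.warning("%s: ranked list too small for GSEA (%d genes); "
                    "writing empty table", path.name, n)
        table = pd.DataFrame(columns=_GSEA_COLUMNS)
    table.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis described by ``config``; returns the run directory."""
    cfg = config.validate()
    if cfg.samples_manifest is None or cfg.gene_panel is None \
            or cfg.gene_sets is None or cfg.reference_profiles is None:
        raise ValueError("samples_manifest, gene_panel, gene_sets and "
                         "reference_profiles are required for a run")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        manifest = read_samples_manifest(cfg.samples_manifest)
        panel = read_gene_panel(cfg.gene_panel)
        collection = read_gmt(cfg.gene_sets)
        reference = read_reference_tsv(cfg.reference_profiles)
        orient_by = (read_gene_panel(cfg.orientation_signature)
                     if cfg.orientation_signature else None)

        exprs, results, cell_counts = {}, {}, {}
        for row in manifest.itertuples(index=False):
            sid = row.sample_id
            try:
                counts = read_10x_mtx(row.path, sample_id=sid, group=row.group)
                qc = compute_cell_qc(counts, mito_prefix=cfg.mito_prefix)
                qc.to_csv(outdir / f"{sid}.qc.tsv", sep="\t")
                filt = filter_cells(counts, qc, min_genes=cfg.min_genes,
                                    max_genes=cfg.max_genes,
                                    max_mito=cfg.max_mito)
                expr = log_normalize(filt.matrix, scale=cfg.scale)
                assign = assign_cell_types(expr, reference)
                nk = extract_cell_type(expr, assign["label"].to_numpy(), "NK")
                res = subcluster_sample(nk, panel, k_min=cfg.k_min,
                                        k_max=cfg.k_max,
                                        seed=cfg.clustering_seed,
                                        n_sd=cfg.outlier_n_sd)
                pd.DataFrame(
                    {"k": list(res.silhouette_by_k),
                     "mean_silhouette": list(res.silhouette_by_k.values())}
                ).to_csv(outdir / f"{sid}.silhouette.tsv", sep="\t", index=False)
                exprs[sid], results[sid] = nk, res
                cell_counts[sid] = {
                    "cells_raw": counts.n_cells, "cells_qc": filt.matrix.n_cells,
                    "nk_cells": nk.n_cells, "chosen_k": res.chosen_k,
                }
            except Exception as exc:  # noqa: BLE001 - stage context wanted
                failed_marker.write_text(f"{sid}: {exc}\n")
                raise PipelineError("per-sample", sid, exc) from exc

        usable = [sid for sid in exprs if results[sid].chosen_k == 2]
        dropped = sorted(set(exprs) - set(usable))
        if dropped:
            log.warning("samples excluded from group contrasts (chosen_k != 2): %s",
                        dropped)
        if len(usable) < 1:
            raise PipelineError("harmonize", "-",
                                ValueError("no sample selected k=2"))

        harm = harmonize_cluster_labels(
            [results[s] for s in usable], [exprs[s] for s in usable],
            exclude_outliers=cfg.exclude_outliers, orient_by=orient_by,
        )
        results.update(dict(zip(usable, harm)))
        for sid in exprs:
            r = results[sid]
            pd.DataFrame(
                {"barcode": r.barcodes, "cluster": r.labels,
                 "distance": r.distances,
                 "outlier": r.outlier_flags.astype(int)}
            ).to_csv(outdir / f"{sid}.clusters.tsv", sep="\t", index=False)

        groups = dict(zip(manifest["sample_id"], manifest["group"]))
        cases = [s for s in usable if groups[s] == "case"]
        controls = [s for s in usable if groups[s] == "control"]
        if not cases:
            raise PipelineError("contrast", "-",
                                ValueError("no usable case sample"))

        # Consensus DE between clusters, excluding the clustering panel.
        de_tables = {}
        for sid in usable:
            r = results[sid]
            de = de_between_clusters(exprs[sid], r.labels,
                                     exclude_genes=r.panel_used,
                                     outlier_flags=r.outlier_flags
                                     if cfg.exclude_outliers else None)
            de.to_csv(outdir / f"{sid}.de.tsv", sep="\t", index=False)
            de_tables[sid] = de
        consensus = consensus_de([de_tables[s] for s in cases],
                                 alpha=cfg.de_alpha,
                                 samples_required=cfg.consensus_samples)
        with open(outdir / "consensus_de_genes.txt", "w") as fh:
            fh.writelines(g + "\n" for g in consensus)
        log.info("consensus DE (non-panel, all %d cases): %d genes",
                 len(cases), len(consensus))

        def ranking(universe, sids, tag):
            if not universe or not sids:
                return None
            try:
                return cluster_contrast_ranking(
                    [exprs[s] for s in sids], [results[s] for s in sids],
                    universe, exclude_outliers=cfg.exclude_outliers, tag=tag)
            except ValueError as exc:
                log.warning("%s ranking unavailable: %s", tag, exc)
                return None

        def cc_ranking(universe, tag):
            if not universe or not cases or not controls:
                return None
            try:
                return case_control_contrast_ranking(
                    [exprs[s] for s in cases], [results[s] for s in cases],
                    [exprs[s] for s in controls], [results[s] for s in controls],
                    universe, mode=cfg.case_control_mode,
                    exclude_outliers=cfg.exclude_outliers, tag=tag)
            except ValueError as exc:
                log.warning("%s ranking unavailable: %s", tag, exc)
                return None

        panel_universe = results[cases[0]].panel_used
        rankings = {
            "panel.cluster_contrast": ranking(panel_universe, cases, "panel"),
            "consensus.cluster_contrast": ranking(consensus, cases, "consensus"),
            "panel.case_vs_control": cc_ranking(panel_universe, "panel"),
            "consensus.case_vs_control": cc_ranking(consensus, "consensus"),
        }
        if not controls:
            log.warning("no usable control sample; case-vs-control tables "
                        "will be empty")
        for name, ranked in rankings.items():
            if ranked is not None:
                ranked.to_frame().to_csv(outdir / f"{name}.rnk",
                                         sep="\t", header=False, index=False)
            _write_gsea(ranked, collection, cfg, outdir / f"gsea.{name}.tsv",
                        seed=cfg.seed)

        run_manifest = {
            "package": "nksub",
            "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "config": asdict(cfg),
            "samples": cell_counts,
            "usable_samples": usable,
            "excluded_samples": dropped,
            "n_consensus_de_genes": len(consensus),
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
        return outdir
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        failed_marker.write_text(str(exc) + "\n")
        raise PipelineError("cohort", "-", exc) from exc
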