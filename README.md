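# nksub

Discovery and characterization of hidden natural killer (NK) cell
subpopulations in PBMC single-cell RNA-seq.

NK cells are innate lymphocytes whose heterogeneity is poorly captured by
conventional marker-based pipelines. `nksub` implements a targeted
subclustering strategy for case/control PBMC cohorts (the motivating
setting is single ventricle / hypoplastic left heart syndrome, SV/HLHS):
instead of clustering cells on a global embedding, NK cells are clustered
**per sample** on a disease-associated gene panel, the per-sample clusters
are harmonized into consistent identities, and the resulting cluster
signatures are contrasted within and between groups by preranked gene-set
enrichment analysis.

## Method

Given per-sample UMI count matrices `X (genes x cells)`, a gene panel `P`,
and a gene-set collection:

1. **QC** — keep cells with `200 < genes detected < 5000` and
   mitochondrial read fraction `< 0.15` (strict bounds).
2. **Normalization** — LogNormalize:
   `x̃_gc = ln(1 + 10^4 · x_gc / Σ_g x_gc)`.
3. **Cell-type assignment** — Spearman correlation of each cell to mean
   reference profiles over one-vs-rest marker genes; argmax wins. NK cells
   are extracted.
4. **Subclustering** — per sample, K-means (k-means++, `n_init=10`,
   `random_state=0`) on `x̃` restricted to `P`, for k = 2…10; the k with
   the highest mean silhouette `s(i) = (b_i − a_i)/max(a_i, b_i)` is
   chosen (ties to the smallest k). Cells with centroid distance
   `d_i > mean(d) + 2·SD(d)` are flagged as outliers.
5. **Harmonization** — cluster labels 0/1 are aligned across samples by
   the sign of the Pearson correlation between per-sample contrast vectors
   `Δ_s = mean(cluster 1) − mean(cluster 0)` over the shared panel.
6. **Differential expression** — pooled-variance two-sample two-tailed
   Student's t-test per gene (panel genes excluded), with a consensus rule:
   a gene counts only if `p < 0.05` with the same direction in every case
   sample.
7. **Enrichment** — preranked GSEA (weighted running-sum ES,
   gene-permutation null, NES, nominal p, permutation FDR q) on four
   rankings: the cluster contrast and the case-minus-control
   "delta of deltas", each on the clustering panel and on the non-panel
   consensus genes.

Because the motivating study's raw data are restricted, the package ships a
seeded synthetic cohort generator (`nksub.synthetic`) that plants a
two-subtype NK compartment with known up-/down-regulated panels — every
stage is tested against that planted truth.

## Worked example

```python
from nksub import *

cfg = default_config()                      # 6 samples, ~700 NK cells each
matrices, truth = generate_cohort(cfg)

m = matrices[0]
filt = filter_cells(m, compute_cell_qc(m))
expr = log_normalize(filt.matrix)
types = (truth.cells.set_index("barcode")["cell_type"]
         .loc[expr.barcodes].to_numpy())
nk = extract_cell_type(expr, types, "NK")
res = subcluster_sample(nk, cfg.clustering_panel, seed=0)
print(res.chosen_k, {k: round(s, 2) for k, s in res.silhouette_by_k.items()})
```

prints

```
2 {2: 0.44, 3: 0.26, 4: 0.25, 5: 0.24, 6: 0.24, 7: 0.01, 8: 0.0, 9: 0.01, 10: 0.0}
```

— the silhouette curve peaks sharply at k = 2, the planted number of NK
subtypes, and `res.labels` recovers the planted partition (adjusted Rand
index 1.0 on this sample). Running the enrichment stage on the case
cluster contrast (`examples/05_consensus_de_and_gsea.py`) yields

```
         set  size     es    nes     p     q
  PLANTED_UP    60  1.000  6.416 0.000 0.000
    DECOY_07    20  0.228  1.086 0.310 0.508
    ...
PLANTED_DOWN    60 -1.000 -6.481 0.000 0.000
```

— the planted up-panel enriches at the top (NES > 0, q < 0.05), the
down-panel at the bottom, and random decoy sets stay insignificant.

The `examples/` directory holds one short script per capability
(simulation, QC, annotation, subclustering, DE + GSEA, full pipeline); a
thin CLI covers the end-to-end path:

```bash
nksub simulate --outdir cohort --seed 0
nksub run --config cohort/config.yaml
```

## Layout

- `src/nksub/` — `matrix_io` (10x MTX / GMT / panel I/O), `synthetic`
  (cohort simulator), `qc_norm`, `annotate`, `subcluster`, `diffexp`,
  `gsea`, `pipeline`, `cli`
- `tests/` — unit, property and end-to-end tests (all synthetic, generated
  at test time)
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
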