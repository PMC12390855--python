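# Methods

This note records what `nksub` computes, the assumptions behind each stage,
the defaults and why they were chosen, and what the synthetic cohort does —
and does not — establish about real data.

## Problem setting

PBMC scRNA-seq cohorts with a handful of case and control samples, where
the question is whether a *specific* transcriptional program (a
disease-associated gene panel) splits the NK compartment into discrete
subpopulations, and whether that split is amplified in cases. Global
clustering pipelines (HVG selection → PCA → graph clustering) answer a
different question — which broad populations exist — and can wash out a
split that lives on a few hundred genes; clustering each sample's NK cells
directly on the panel is the method's core move.

## Stages, assumptions, parameters

### QC and normalization
Cells are kept when `min_genes < detected < max_genes` and
`mito_fraction < max_mito`, defaults 200 / 5 000 / 0.15, all three bounds
strict. Whether a cell at exactly 15% mitochondrial reads should pass is
genuinely ambiguous in the protocol the defaults come from; strictness was
chosen for all three bounds for consistency and is configurable.
Mitochondrial genes are recognized by the `MT-` symbol prefix (GRCh38
convention, configurable). Normalization is LogNormalize with scale 10 000
and the **natural** logarithm of (1 + value); zero counts stay exactly
zero, so sparsity is preserved.

### Cell-type assignment
A deliberately simple one-round annotator: Spearman correlation (average
ranks on ties) of each cell against per-type mean log-normalized profiles,
over marker genes. Marker default: the union over types of each type's top
50 genes by one-vs-rest profile excess. A plain top-50-by-variance rule
was rejected because overall variance is dominated by a few highly
expressed genes and can leave a type with no markers at all; the
one-vs-rest union guarantees every type contributes. No iterative
fine-tuning, no per-reference-cell quantile aggregation, no score pruning:
the package's contribution is downstream of annotation, and the simulator's
planted truth makes this surrogate directly verifiable (per-cell accuracy
≥ 99% on well-separated synthetic types is part of the test suite). Cells
constant across marker genes are labeled `unassigned`.

### Subclustering and model selection
Feature space: unscaled log-normalized expression restricted to
panel ∩ matrix genes, Euclidean metric — no z-scaling, no PCA. K-means uses
k-means++ initialization, `n_init=10` keep-best restarts, `max_iter=300`,
`tol=1e-4`, fixed `random_state` (default 0); these are scikit-learn's
semantics and defaults, which is the implementation used. Candidate
k = 2…10 are scored by mean silhouette with two conventions: cells in
singleton clusters score 0, and 0/0 (coincident points) scores 0. Ties
across k break toward the smallest k (parsimony). With fewer than 11
cells, k_max is capped at n − 1 with a warning.

### Outliers
A cell is an outlier when its Euclidean distance to its own centroid
strictly exceeds mean + 2 SD of **all pooled** distances, with the
population (n) denominator. Pooling across clusters treats "distance to
centroid" as one global distribution; a per-cluster variant would flag
relative to each cluster's own spread and is a possible extension, but the
pooled rule is the simpler reading of a single 2-SD cutoff. Outliers are
excluded from downstream contrast means and DE by default (configurable):
flagged-but-kept cells would drag cluster means exactly where the flag says
they do not belong.

### Harmonization
K-means labels carry no meaning across samples, so cross-sample contrasts
need an alignment step. Per sample the contrast vector
Δ_s = mean(cluster 1) − mean(cluster 0) over the shared panel genes is
computed (outliers excluded); the first sample anchors the coding and any
sample whose Δ correlates negatively (Pearson) with the anchor's is
flipped. This leaves one global degree of freedom — which state is called
"cluster 1" — that the anchor fixes arbitrarily, exactly as in the
motivating analyses where cluster numbering is an artifact of the fit. An
optional `orient_by` gene list resolves it deterministically: the global
sign is chosen so those genes are up in cluster 1 on average. The
synthetic tests pass the planted up-panel here, pinning cluster 1 to the
planted subtype 1. Harmonization requires k = 2 in every participating
sample; samples that selected a different k are excluded from group
contrasts with a loud warning rather than silently forced (a forced fit
would hide a model-selection failure).

### Differential expression and consensus
Per gene, a pooled-variance two-sample two-tailed Student's t-test
(df = n₁ + n₀ − 2) on log-normalized values, cluster 1 vs cluster 0,
excluding the clustering panel — testing the panel against labels derived
from it would be circular. Degenerate convention: zero pooled variance
gives (t=0, p=1) when means agree and (±∞, 0) otherwise. No
multiple-testing correction is applied inside the per-gene test; the
consensus rule (p < α with the same sign in *every* required sample,
default α = 0.05, all case samples) and the permutation FDR of the
enrichment stage are the operative error controls. A BH-adjusted column is
emitted for transparency. Marker-gene filtering uses min.pct = 0.25
(detection fraction in at least one of the two groups) and |log2FC| > 0.25
computed on expm1-backtransformed means with pseudocount 1.

### Ranked contrasts
`cluster_contrast_ranking` scores each gene by Δ averaged over samples;
`case_control_contrast_ranking` defaults to the "delta of deltas"
(mean case Δ − mean control Δ). An alternative `cluster1_profile` mode
(mean cluster-1 expression, cases minus controls) is provided because the
case-vs-control contrast family can be read either way; the mode is
recorded in the output and neither is asserted as canonical. Ranking ties
break lexicographically by gene symbol so output is deterministic.

### Preranked GSEA
Written from scratch. Walking the ranked list, hits add
|score|^p / Σ_hits |score|^p (p = 1, the weighted default) and misses
subtract 1/(N − N_hits); ES is the running-sum value of maximal absolute
deviation, earliest position on ties. If every hit score is zero, hits add
1/N_hits (degenerate unweighted rule). The null is **gene-label
permutation**: set membership is reassigned uniformly among ranked genes,
preserving set size. This is forced by the input being a precomputed
ranked list — per-sample phenotype shuffling cannot be reconstructed from
it — and it makes the null narrower than a phenotype-permutation null;
nominal p and FDR q are interpretable relative to that null only.
NES = ES / mean(|null ES| of the same sign); nominal p is the same-sign
null tail fraction; q compares the pooled null NES distribution against
the observed NES distribution (clipped to [0, 1]) and is forced monotone
within each sign class. Set-size bounds 15–500 after universe
intersection, 1 000 permutations by default; a q of 0 means "below
1/n_perm". The fast vectorized permutation scorer evaluates the running
sum only at hit-adjacent positions (where its extrema occur) and is tested
to 1e-12 against the definitional full walk.

## The synthetic cohort

`default_config()` defines the package's reference conditions: 3 case +
3 control samples, 2 000 cells each over 1 000 genes (13 `MT-`), cell-type
proportions NK 0.35 / T 0.35 / B 0.15 / Mono 0.15, NK subtype-1 fraction
0.45, a 120-gene clustering panel (60 up + 60 down), base effect 1.0 in
natural-log units doubled in cases, NB dispersion 0.3, log-normal library
sizes (meanlog 8.0, sdlog 0.3), seed 0. The NK proportion and cell count
put the expected NK yield at 700 per sample — inside the 548–939 range the
method targets — while keeping a full run desk-scale (the pipeline on the
default cohort takes well under a minute); total PBMC counts per sample
are smaller than in real 10x runs.

Counts are gamma–Poisson around type-specific relative expression profiles
scaled by the cell's library factor; each cell type gets 40 marker genes
at 8× baseline; mitochondrial means are scaled to a ~5% expected read
share. Subtype-1 NK cells have panel-gene means multiplied by exp(±effect)
*without* renormalizing the cell's total — so the planted shift also
perturbs the cell's library composition, and per-cell normalization then
dilutes non-panel genes in subtype-1 cells. This compositional spillover
is deliberate and realistic (CPM-style normalization has exactly this
property), and it is what gives the non-panel consensus-DE stage a
non-empty gene list to find on synthetic data. One RNG stream per sample
is derived from (seed, sample index), so cohorts are bit-reproducible and
independent of iteration order.

What the simulator does **not** emulate: transcriptome-wide co-expression
structure, batch effects, doublets, ambient RNA, and continuous (rather
than discrete) NK states. Passing tests therefore establish correctness of
the machinery and recoverability of a planted discrete two-state signal at
the stated effect sizes — not that real NK compartments contain such
states, nor the method's behavior under gradual transitions.

## Numerical and degenerate-input conventions

- Matrix Market triplets are 1-based on disk, 0-based in memory; counts
  must be nonnegative integers, zeros implicit. Gzipped inputs are read
  transparently.
- Gene identity is the case-sensitive symbol string; no alias resolution.
- All-zero cells get mito_fraction 0 in QC; they cannot be normalized
  (error directing to filter first).
- `flag_outliers` on < 2 cells returns no flags with a warning.
- Empty gene panels, empty gene sets, sets covering the whole universe,
  and clusters with < 2 cells are errors, not silent degradation.
- Pipeline reruns with an identical config are byte-identical across all
  result tables; the run manifest records config, versions, and per-stage
  cell counts.

## Known limitations

- The annotator is a surrogate for reference-based tools with fine-tuning;
  on real data with closely related types (e.g., NK vs NKT vs γδ T) its
  accuracy is untested here.
- Silhouette model selection compares k ≥ 2 only; "no substructure at all"
  (k = 1) is outside the candidate set, consistent with the question the
  method asks, but a low best silhouette should be read as weak evidence.
- The gene-permutation GSEA null ignores inter-gene correlation, which
  typically makes nominal p optimistic for coherently co-expressed sets;
  the case/control contrast of significance levels is more robust than any
  single q-value.
- The consensus-DE rule's α and direction requirement are conventions
  (configurable), not derived thresholds.
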