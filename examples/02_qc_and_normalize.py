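"""Cell-level QC and LogNormalize on one synthetic sample.

Cells pass QC with >200 and <5,000 detected genes and <15% mitochondrial
reads; surviving counts are normalized per cell to 10,000 and log1p'd.
"""

from nksub import (compute_cell_qc, default_config, filter_cells,
                   generate_cohort, inject_qc_violations, log_normalize)

matrices, _ = generate_cohort(default_config())
sample = matrices[0]

# Plant a few violators so the filter has something to reject.
sample, planted = inject_qc_violations(sample, n_low=3, n_high=0, n_mito=2,
                                       seed=1)
qc = compute_cell_qc(sample)
print("QC summary (per cell):")
print(qc.describe().loc[["mean", "min", "max"]].round(3), "\n")

result = filter_cells(sample, qc)
print(f"retained {result.matrix.n_cells}/{sample.n_cells} cells; "
      f"rejections by rule: {result.tallies}")
print(f"planted violators rejected: "
      f"{set().union(*planted.values()) <= set(sum(result.rejected.values(), []))}\n")

expr = log_normalize(result.matrix)
v = expr.values[:, 0].toarray().ravel()
print(f"normalized values, cell 1: min {v.min():.3f}, max {v.max():.3f} "
      f"(natural-log scale, zeros stay zero)")
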