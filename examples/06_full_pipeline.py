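"""Run the whole analysis end to end from files on disk.

Writes a simulated cohort as 10x-style directories plus panel/GMT/reference
inputs, then executes the pipeline exactly as `nksub run` would.
"""

import tempfile
from pathlib import Path

from nksub import default_config, prepare_run_directory, run_pipeline, \
    validate_config

with tempfile.TemporaryDirectory() as tmp:
    cohort = Path(tmp) / "cohort"
    prepare_run_directory(default_config(), cohort)
    print(f"inputs written to {cohort}:")
    for p in sorted(cohort.iterdir()):
        print("  ", p.name)

    config = validate_config(cohort / "config.yaml")
    outdir = run_pipeline(config)

    print(f"\nrun outputs in {outdir}:")
    for p in sorted(outdir.iterdir()):
        print("  ", p.name)

    head = (outdir / "gsea.panel.cluster_contrast.tsv").read_text().splitlines()
    print("\ngsea.panel.cluster_contrast.tsv (first rows):")
    print("\n".join(head[:4]))

# Per sample there is a QC table, a silhouette-vs-k curve and a
# cluster/outlier assignment; cohort-wide there are ranked lists and four
# GSEA tables (cluster contrast and case-vs-control, each on the clustering
# panel and on the non-panel consensus DE genes).
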