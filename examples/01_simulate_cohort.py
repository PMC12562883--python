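"""Simulate a melanoma-like cohort with planted clonal CNVs.

Builds the bundled default configuration — a diploid reference population
(normal melanocytes) plus three tumor clones carrying 0, 1 and 3 arm-level
copy-number events — samples the count matrix, and writes a CellRanger-style
plain-text fixture.
"""

from pathlib import Path

import cnvscape as cs

cfg = cs.default_config(seed=0)
ann = cs.simulate_gene_annotation(cfg.n_chromosomes, cfg.genes_per_arm, seed=0)
adata, truth = cs.simulate_counts(cfg, ann)

print(f"cells x genes: {adata.shape}")
print(truth.cells.groupby(["clone", "activity"]).size().unstack(fill_value=0))
events = truth.clone_arms.query("copy_number != 2")
print("planted arm events:")
print(events.to_string(index=False))

out = Path("scratch/example_fixture")
manifest = cs.write_fixture(adata, truth, out, overwrite=True)
print(f"wrote {len(manifest['files'])} files to {out}")

# The table above is the ground truth the analysis must recover: each row
# of `events` is an arm whose dosage deviates from the diploid 2 copies,
# and the activity column marks cells over-expressing the activity sets.
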