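"""Differential expression and the DEG-with-CNV intersection.

Tests every gene tumor-vs-reference with a two-sided Wilcoxon rank-sum
(|log2FC| >= 0.25, BH-adjusted p < 0.05, both directions), then keeps the
genes that also carry a copy-number event in at least 30% of tumor cells —
the input of an arm-annotated "DEG with CNV" landscape.
"""

import numpy as np

import cnvscape as cs

cfg = cs.default_config(seed=0)
ann = cs.simulate_gene_annotation(cfg.n_chromosomes, cfg.genes_per_arm, seed=0)
adata, _ = cs.simulate_counts(cfg, ann)
adata, _ = cs.qc_filter(adata)
X = cs.normalize_log(adata.X, cell_ids=adata.obs_names)
ref = (adata.obs["group"] == "reference").to_numpy()
# compare the clone carrying the 4-copy 1q amplification to the reference
carriers = (adata.obs["clone"] == "clone_mid").to_numpy()

degs = cs.wilcoxon_de(X, adata.var_names, carriers, ref)
print(f"{len(degs)} DEGs at |log2FC| >= 0.25 and adjusted p < 0.05")
print(degs.head(3).to_string(index=False))

annotation = adata.var.reset_index().rename(columns={"index": "gene_id"})
smoothed, kept = cs.smooth_relative_expression(X, annotation, ref)
states = cs.call_states(smoothed, ref)
with_cnv = cs.intersect_deg_cnv(degs, states, kept["gene_id"], carriers)
print(f"\n{len(with_cnv)} DEGs carry a CNV event in >= 30% of carrier cells")
print(with_cnv.head(3).to_string(index=False))

gained = with_cnv[with_cnv["cnv_direction"] == "gain"]
on_1q = kept.set_index("gene_id").loc[gained["gene"], "arm"] == "1q"
print(f"\n{len(gained)} of them sit on gained segments; "
      f"{on_1q.mean():.0%} of those are on the amplified arm 1q")

# Genes that are both differentially expressed and recurrently altered in
# copy number are the dosage-driven candidates; up-regulation coinciding
# with gains is the expected dosage signature.
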