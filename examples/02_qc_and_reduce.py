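"""Quality control, normalisation, variable genes and significant PCs.

Filters cells on UMI count, expressed-gene count and mitochondrial
percentage, library-normalises and log-transforms the counts, ranks genes
by variance-stabilised dispersion, and picks the number of informative
principal components from the variance spectrum.
"""

import cnvscape as cs

cfg = cs.default_config(seed=0)
ann = cs.simulate_gene_annotation(cfg.n_chromosomes, cfg.genes_per_arm, seed=0)
adata, _ = cs.simulate_counts(cfg, ann)

adata, report = cs.qc_filter(adata, cs.QCThresholds(min_umi=300, max_mito_pct=20))
print(f"QC: kept {report.n_after} of {report.n_before} cells")

X = cs.normalize_log(adata.X, scale_factor=10_000, cell_ids=adata.obs_names)
hvgs = cs.select_hvg(X, adata.var_names, n_top=200)
print(f"top variable genes: {hvgs[:5]} ...")

embedding, spectrum = cs.run_pca(X, adata.var_names.get_indexer(hvgs),
                                 n_components=30)
k = cs.select_significant_pcs(spectrum)
print(f"variance explained by first 5 PCs (%): {spectrum[:5].round(2)}")
print(f"significant PCs: {k}")

# `k` is where the spectrum stops carrying structure: later components
# explain little additional variance, so downstream neighbourhood-based
# statistics (e.g. iLISI) use only the first k coordinates.
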