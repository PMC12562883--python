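import numpy as np
import pytest

import cnvscape as cs


@pytest.fixture(scope="session")
def default_sim():
    """The bundled study cohort: 3 clones (0/1/3 altered arms), 2 batches."""
    cfg = cs.default_config(seed=11)
    ann = cs.simulate_gene_annotation(cfg.n_chromosomes, cfg.genes_per_arm, seed=11)
    adata, truth = cs.simulate_counts(cfg, ann)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def processed(default_sim):
    """QC-filtered, normalised, CNV-smoothed view of the default cohort."""
    _, adata, truth = default_sim
    adata, _ = cs.qc_filter(adata)
    X = cs.normalize_log(adata.X, cell_ids=adata.obs_names)
    ref = (adata.obs["group"] == "reference").to_numpy()
    ann = adata.var.reset_index().rename(columns={"index": "gene_id"})
    smoothed, kept = cs.smooth_relative_expression(X, ann, ref)
    states = cs.call_states(smoothed, ref)
    return {
        "adata": adata,
        "truth": truth,
        "X": X,
        "ref": ref,
        "ann": ann,
        "smoothed": smoothed,
        "kept": kept,
        "states": states,
        "scores": cs.cell_cnv_score(states),
    }


@pytest.fixture(scope="session")
def null_sim():
    """Same cohort shape with no planted CNV events anywhere."""
    cfg = cs.default_config(seed=13)
    for clone in cfg.clones:
        clone.arm_events = {}
    ann = cs.simulate_gene_annotation(cfg.n_chromosomes, cfg.genes_per_arm, seed=13)
    adata, truth = cs.simulate_counts(cfg, ann)
    return cfg, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
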