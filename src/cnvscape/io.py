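"""Reading and writing fixtures in CellRanger-style plain-text formats.

A fixture directory holds ``matrix.mtx`` (genes x cells, 1-based Matrix
Market, integer field), ``barcodes.tsv``, ``features.tsv`` (id, symbol,
feature type), a gene annotation TSV, a GMT gene-set file, ground-truth
TSVs and a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .simulate import SimulationTruth

__all__ = [
    "write_fixture",
    "read_fixture",
    "read_gmt",
    "write_gmt",
]

_ANNOTATION_COLS = ["gene_id", "chrom", "arm", "start", "rank"]


def write_gmt(gene_sets: dict[str, list[str]], path: Path | str) -> None:
    """Write gene sets in GMT: name, description, then tab-separated genes."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def read_gmt(path: Path | str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT record: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_fixture(
    adata: AnnData,
    truth: SimulationTruth,
    out_dir: Path | str,
    overwrite: bool = False,
) -> dict:
    """Write a simulated dataset as a plain-text fixture; returns the manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)

    X = sp.csr_matrix(adata.X)
    # CellRanger orientation: genes x cells
    scipy.io.mmwrite(out / "matrix.mtx", X.T.tocoo(), field="integer")
    adata.obs_names.to_series().to_csv(out / "barcodes.tsv", header=False, index=False)
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "symbol": adata.var["symbol"]
            if "symbol" in adata.var
            else adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)

    ann = adata.var.reset_index().rename(columns={"index": "gene_id"})
    ann[_ANNOTATION_COLS].to_csv(out / "annotation.tsv", sep="\t", index=False)

    cells = adata.obs.reset_index()
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)

    write_gmt(truth.gene_sets, out / "gene_sets.gmt")
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    truth.clone_arms.to_csv(out / "truth_clone_arms.tsv", sep="\t", index=False)

    manifest = {
        "files": {
            "matrix.mtx": {"rows": int(X.shape[1]), "cols": int(X.shape[0])},
            "barcodes.tsv": {"rows": int(X.shape[0]), "cols": 1},
            "features.tsv": {"rows": int(X.shape[1]), "cols": 3},
            "annotation.tsv": {"rows": int(X.shape[1]), "cols": len(_ANNOTATION_COLS)},
            "cells.tsv": {"rows": int(X.shape[0]), "cols": int(cells.shape[1])},
            "gene_sets.gmt": {"rows": len(truth.gene_sets), "cols": None},
            "truth_cells.tsv": {
                "rows": int(truth.cells.shape[0]),
                "cols": int(truth.cells.shape[1]),
            },
            "truth_clone_arms.tsv": {
                "rows": int(truth.clone_arms.shape[0]),
                "cols": int(truth.clone_arms.shape[1]),
            },
        },
        "n_cells": int(X.shape[0]),
        "n_genes": int(X.shape[1]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture(in_dir: Path | str) -> tuple[AnnData, SimulationTruth]:
    """Read a fixture directory back into (AnnData, SimulationTruth)."""
    d = Path(in_dir)
    M = scipy.io.mmread(d / "matrix.mtx")  # genes x cells
    X = sp.csr_matrix(M.T).astype(np.int64)
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None)[0].astype(str)
    feats = pd.read_csv(
        d / "features.tsv", sep="\t", header=None,
        names=["gene_id", "symbol", "feature_type"],
    )
    ann = pd.read_csv(d / "annotation.tsv", sep="\t", dtype={"chrom": str})
    var = ann.set_index("gene_id")
    var["symbol"] = feats.set_index("gene_id")["symbol"]
    var["is_mito"] = var["symbol"].str.startswith("MT-")
    cells = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0, dtype=str)
    for col in ("mito_pct_true",):
        if col in cells:
            cells[col] = cells[col].astype(float)
    cells.index.name = "cell_id"
    adata = AnnData(X=X, obs=cells.loc[barcodes.to_numpy()], var=var)

    truth = SimulationTruth(
        cells=pd.read_csv(d / "truth_cells.tsv", sep="\t", dtype=str),
        clone_arms=pd.read_csv(d / "truth_clone_arms.tsv", sep="\t"),
        gene_sets=read_gmt(d / "gene_sets.gmt"),
    )
    return adata, truth
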