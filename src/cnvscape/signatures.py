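"""Per-cell AUC gene-set scoring and active/inactive state classification.

The score of a gene set in a cell is the area under the set's recovery
curve within the top-ranked fraction of that cell's expression ranking,
normalised by the maximal achievable area — a rank-based statistic in
[0, 1] that is invariant to any monotone transform of the cell's
expression vector. Tumor cells are then labelled active or inactive from
the four activity signatures (proliferation, DNA repair, DNA damage, cell
cycle) via a composite score and a 1-D two-means split.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["aucell_score", "score_gene_sets", "classify_activity"]

ACTIVITY_SETS = ("proliferation", "dna_repair", "dna_damage", "cell_cycle")


def aucell_score(
    X_norm: np.ndarray,
    gene_names,
    gene_set,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell recovery-curve AUC of ``gene_set`` in the top ranks.

    Per cell, all G genes are ranked by descending expression (ties broken
    by a seeded random permutation shared across cells); with T =
    ceil(top_fraction * G), the recovery curve counts set genes among the
    top k ranks for k = 1..T and the score is its area divided by the
    maximal area (all set genes at the very top). Empty intersection with
    the matrix's genes scores 0 with a warning.
    """
    X = np.asarray(X_norm, dtype=float)
    genes = np.asarray(gene_names)
    G = X.shape[1]
    T = math.ceil(top_fraction * G)
    if T < 1:
        raise ValueError("top_fraction too small: top rank window is empty")
    member = np.isin(genes, np.asarray(list(gene_set)))
    m = int(member.sum())
    if m == 0:
        warnings.warn("gene set does not intersect the matrix genes; scores are 0",
                      stacklevel=2)
        return np.zeros(X.shape[0])

    rng = np.random.default_rng(seed)
    tie_key = rng.permutation(G)
    # ranks: 0 = highest expression; lexsort's last key is primary
    order = np.lexsort((np.broadcast_to(tie_key, X.shape), -X), axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(G), X.shape), axis=1)

    hit_ranks = ranks[:, member]  # cells x m
    contrib = np.clip(T - hit_ranks, 0, None)  # (T - r) for r < T, else 0
    auc = contrib.sum(axis=1)
    max_auc = sum(T - j for j in range(min(m, T)))
    return auc / max_auc


def score_gene_sets(
    X_norm: np.ndarray,
    gene_names,
    gene_sets: dict[str, list[str]],
    top_fraction: float = 0.05,
    seed: int = 0,
    cell_ids=None,
) -> pd.DataFrame:
    """Score several gene sets; returns a cells x sets DataFrame in [0, 1]."""
    scores = {
        name: aucell_score(X_norm, gene_names, genes, top_fraction, seed)
        for name, genes in gene_sets.items()
    }
    return pd.DataFrame(scores, index=cell_ids)


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        warnings.warn("constant signature column; contributes 0.5 uniformly",
                      stacklevel=3)
        return np.full(col.shape, 0.5)
    return (col - lo) / (hi - lo)


def classify_activity(
    scores: pd.DataFrame,
    activity_sets=ACTIVITY_SETS,
    mode: str = "kmeans",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Label each cell active or inactive from the activity signatures.

    Each signature column is min-max scaled over the given cells and the
    composite score is their mean. In ``kmeans`` mode a 1-D two-means split
    (centroids initialised at the composite min and max) separates the
    cells and the cluster with the larger centroid is "active"; if the
    composite is constant, every cell is inactive (with a warning). In
    ``threshold`` mode cells with composite >= ``threshold`` are active.

    Returns a DataFrame with columns ``composite`` and ``activity``.
    """
    missing = [s for s in activity_sets if s not in scores.columns]
    if missing:
        raise ValueError(f"missing signature columns: {missing}")
    if len(scores) < 4:
        raise ValueError("need >= 4 cells to classify activity")
    scaled = np.column_stack(
        [_minmax(scores[s].to_numpy(dtype=float)) for s in activity_sets]
    )
    composite = scaled.mean(axis=1)

    if mode == "threshold":
        active = composite >= threshold
    elif mode == "kmeans":
        c0, c1 = composite.min(), composite.max()
        if c1 == c0:
            warnings.warn("constant composite score; all cells inactive",
                          stacklevel=2)
            active = np.zeros(len(composite), dtype=bool)
        else:
            for _ in range(100):
                assign = np.abs(composite - c1) < np.abs(composite - c0)
                n0, n1 = c0, c1
                if assign.any():
                    n1 = composite[assign].mean()
                if (~assign).any():
                    n0 = composite[~assign].mean()
                if n0 == c0 and n1 == c1:
                    break
                c0, c1 = n0, n1
            active = assign if c1 >= c0 else ~assign
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return pd.DataFrame(
        {
            "composite": composite,
            "activity": pd.Categorical(
                np.where(active, "active", "inactive"),
                categories=["inactive", "active"],
            ),
        },
        index=scores.index,
    )
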