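"""Wilcoxon differential expression and the DEG-with-CNV intersection.

Genes are tested tumor-vs-reference with a two-sided Wilcoxon rank-sum on
normalised expression (exact null when both groups have <= 8 tie-free
observations, tie-corrected normal approximation otherwise), p-values are
Benjamini–Hochberg adjusted, and genes pass with |log2FC| >= 0.25 and
adjusted p < 0.05, both directions reported. Fold changes are computed on
de-logged means: log2((mean expm1(a) + eps) / (mean expm1(b) + eps)).

A "DEG with CNV" is a differentially expressed gene that also carries a
copy-number event in at least ``min_cnv_fraction`` of the tumor cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cnv import CNVState, GAIN_STATES, weight_lookup

__all__ = ["bh_adjust", "wilcoxon_de", "intersect_deg_cnv"]

_EPS = 1e-9


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(log2fc: np.ndarray) -> np.ndarray:
    out = np.full(log2fc.shape, "none", dtype=object)
    out[log2fc > 1] = "up"
    out[log2fc < -1] = "down"
    return out


def wilcoxon_de(
    X_norm: np.ndarray,
    gene_names,
    group_a,
    group_b,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group DE: group_a vs group_b (log2FC > 0 means higher in a).

    ``group_a``/``group_b`` are disjoint row index arrays (or boolean
    masks). Returns the genes with |log2FC| >= ``logfc_threshold`` and BH
    adjusted p < ``alpha``, sorted by adjusted p then gene name, with
    columns gene, log2fc, p, p_adj, direction (up/down/none by the strict
    |log2FC| > 1 rule used for the landscape).
    """
    X = np.asarray(X_norm, dtype=float)
    a_idx = _as_index(group_a, X.shape[0])
    b_idx = _as_index(group_b, X.shape[0])
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")
    if a_idx.size < 3 or b_idx.size < 3:
        raise ValueError("both groups need >= 3 cells")
    A, B = X[a_idx], X[b_idx]

    if max(a_idx.size, b_idx.size) <= 8:
        p = np.array([_small_sample_p(A[:, j], B[:, j]) for j in range(X.shape[1])])
    else:
        p = mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)[1]

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + _EPS) / (mean_b + _EPS))
    p_adj = bh_adjust(p)

    res = pd.DataFrame(
        {
            "gene": np.asarray(gene_names),
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": _direction(log2fc),
        }
    )
    res = res[(np.abs(res["log2fc"]) >= logfc_threshold) & (res["p_adj"] < alpha)]
    return res.sort_values(["p_adj", "gene"], kind="stable").reset_index(drop=True)


def _small_sample_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null only holds without ties; fall back to the tie-corrected
    # normal approximation when the pooled sample has ties
    method = "exact" if np.unique(np.concatenate([a, b])).size == a.size + b.size \
        else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method)[1])


def _as_index(sel, n: int) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.size != n:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(sel)
    return sel.astype(int)


def intersect_deg_cnv(
    degs: pd.DataFrame,
    states: np.ndarray,
    state_genes,
    tumor_mask,
    weights=None,
    min_cnv_fraction: float = 0.3,
) -> pd.DataFrame:
    """Restrict DEGs to genes with a CNV event in the tumor population.

    A gene qualifies when its state is non-neutral in at least
    ``min_cnv_fraction`` of tumor cells. The dominant direction is the one
    (gain vs loss) with the larger summed event weight across tumor cells
    (ties resolve to gain), and the dominant weight is the weight of the
    most frequent non-neutral state in that direction.
    """
    tumor = np.asarray(tumor_mask, dtype=bool)
    if not tumor.any():
        raise ValueError("tumor group is empty")
    S = np.asarray(states)[tumor]
    gene_pos = {g: j for j, g in enumerate(np.asarray(state_genes))}
    table = weight_lookup(weights)
    gain_codes = {int(s) for s in GAIN_STATES}

    rows = []
    for _, rec in degs.iterrows():
        j = gene_pos.get(rec["gene"])
        if j is None:
            continue
        col = S[:, j]
        non_neutral = col != int(CNVState.NEUTRAL)
        frac = float(non_neutral.mean())
        if frac < min_cnv_fraction:
            continue
        if not non_neutral.any():  # only reachable at min_cnv_fraction = 0
            rows.append({**rec.to_dict(), "cnv_fraction": 0.0,
                         "cnv_direction": "none", "cnv_weight": 0})
            continue
        w = table[col.astype(np.int64)]
        is_gain = np.isin(col, list(gain_codes))
        gain_sum = int(w[is_gain].sum())
        loss_sum = int(w[non_neutral & ~is_gain].sum())
        dominant = "gain" if gain_sum >= loss_sum else "loss"
        dom_mask = non_neutral & (is_gain if dominant == "gain" else ~is_gain)
        if not dom_mask.any():  # all event weights zero under a custom map
            dom_mask = non_neutral
        dom_states, counts = np.unique(col[dom_mask], return_counts=True)
        dom_state = int(dom_states[np.argmax(counts)])
        rows.append(
            {
                **rec.to_dict(),
                "cnv_fraction": frac,
                "cnv_direction": dominant,
                "cnv_weight": int(table[dom_state]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[*degs.columns, "cnv_fraction", "cnv_direction", "cnv_weight"],
    )
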