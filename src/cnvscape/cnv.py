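"""Reference-anchored CNV inference from expression and event scoring.

The pipeline mirrors the standard expression-based CNV workflow: genes are
ordered along the genome, each cell's normalised expression is expressed as
a residual against the mean of a diploid reference population (normal
melanocytes), residuals are clamped, smoothed by a moving average along
each chromosome, re-centred per cell, and quantised into six discrete
copy-number states. Events are then scored with integer weights

    multi_copy_gain (> two copies gained) -> 3
    two_copy_gain                         -> 2
    one_copy_gain                         -> 1
    one_copy_loss                         -> 1
    complete_loss                         -> 2
    neutral                               -> 0

summed per cell (the CNV score), classified into low/medium/high degrees
against the reference score distribution, and aggregated per chromosome
arm into a gain/loss landscape.
"""

from __future__ import annotations

import warnings
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "CNVState",
    "DEFAULT_WEIGHTS",
    "smooth_relative_expression",
    "call_states",
    "state_weight",
    "weight_lookup",
    "cell_cnv_score",
    "classify_cnv_level",
    "arm_event_landscape",
]


class CNVState(IntEnum):
    """Six discrete copy-number states; NEUTRAL is the unique zero-weight one."""

    COMPLETE_LOSS = 0
    ONE_COPY_LOSS = 1
    NEUTRAL = 2
    ONE_COPY_GAIN = 3
    TWO_COPY_GAIN = 4
    MULTI_COPY_GAIN = 5


DEFAULT_WEIGHTS: dict[CNVState, int] = {
    CNVState.MULTI_COPY_GAIN: 3,
    CNVState.TWO_COPY_GAIN: 2,
    CNVState.ONE_COPY_GAIN: 1,
    CNVState.ONE_COPY_LOSS: 1,
    CNVState.COMPLETE_LOSS: 2,
    CNVState.NEUTRAL: 0,
}

GAIN_STATES = (CNVState.ONE_COPY_GAIN, CNVState.TWO_COPY_GAIN, CNVState.MULTI_COPY_GAIN)
LOSS_STATES = (CNVState.ONE_COPY_LOSS, CNVState.COMPLETE_LOSS)


def weight_lookup(weights: dict[CNVState, int] | None = None) -> np.ndarray:
    """State-code -> weight lookup vector; validates the weight map."""
    w = DEFAULT_WEIGHTS if weights is None else weights
    if set(w) != set(CNVState):
        raise ValueError("weight map must cover all six states")
    if w[CNVState.NEUTRAL] != 0:
        raise ValueError("neutral weight must be 0")
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be non-negative")
    table = np.zeros(len(CNVState), dtype=np.int64)
    for state, v in w.items():
        table[int(state)] = int(v)
    return table


def state_weight(state: CNVState, weights: dict[CNVState, int] | None = None) -> int:
    return int(weight_lookup(weights)[int(state)])


def _moving_average_blocks(R: np.ndarray, chrom: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along genes within each chromosome block.

    The window shrinks at chromosome ends: position j averages over
    [j-h, j+h] intersected with the chromosome.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return R.copy()
    h = window // 2
    out = np.empty_like(R)
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        block = R[:, cols]
        m = block.shape[1]
        cs = np.zeros((R.shape[0], m + 1))
        np.cumsum(block, axis=1, out=cs[:, 1:])
        lo = np.maximum(np.arange(m) - h, 0)
        hi = np.minimum(np.arange(m) + h + 1, m)
        out[:, cols] = (cs[:, hi] - cs[:, lo]) / (hi - lo)
    return out


def smooth_relative_expression(
    X_norm: np.ndarray,
    annotation: pd.DataFrame,
    reference_mask,
    min_mean_cutoff: float = 0.1,
    window: int = 101,
    clamp: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Reference-relative, clamped, genomically smoothed residual matrix.

    Steps: drop genes whose mean normalised expression over all cells is
    below ``min_mean_cutoff``; subtract the per-gene reference mean; clamp
    residuals at +-``clamp`` reference-residual SDs; moving-average over
    ``window`` genes along genomic rank within each chromosome; re-centre
    every cell at its median residual (so reference cells sit at 0 by
    construction).

    Returns the smoothed matrix and the annotation rows of retained genes,
    in genomic order.
    """
    ref = np.asarray(reference_mask, dtype=bool)
    if ref.sum() < 10:
        raise ValueError(f"need >= 10 reference cells, got {int(ref.sum())}")
    X = np.asarray(X_norm, dtype=float)
    if len(annotation) != X.shape[1]:
        raise ValueError("annotation rows must match matrix columns")

    order = np.argsort(annotation["rank"].to_numpy(), kind="stable")
    ann = annotation.iloc[order].reset_index(drop=True)
    X = X[:, order]

    keep = X.mean(axis=0) >= min_mean_cutoff
    X, ann = X[:, keep], ann[keep].reset_index(drop=True)
    if X.shape[1] == 0:
        raise ValueError("no genes pass the expression cutoff")

    R = X - X[ref].mean(axis=0)
    ref_sd = R[ref].std()
    if ref_sd > 0:
        lim = clamp * ref_sd
        np.clip(R, -lim, lim, out=R)

    S = _moving_average_blocks(R, ann["chrom"].to_numpy(), window)
    S -= np.median(S, axis=1, keepdims=True)
    return S, ann


def call_states(
    smoothed: np.ndarray,
    reference_mask,
    sd_multipliers: tuple[float, float, float] = (2.5, 4.0, 5.5),
) -> np.ndarray:
    """Quantise smoothed residuals into six states against the reference SD.

    With sigma the pooled SD of reference residuals and (a, b, c) the
    multipliers: |r| < a*sigma is neutral; a*sigma <= |r| < b*sigma is a
    one-copy event; b*sigma <= r < c*sigma is a two-copy gain and r >=
    c*sigma a multi-copy gain; losses at or below -b*sigma saturate at
    complete loss. Boundaries map to the higher-magnitude state.
    """
    S = np.asarray(smoothed, dtype=float)
    ref = np.asarray(reference_mask, dtype=bool)
    a, b, c = sd_multipliers
    if not 0 < a < b < c:
        raise ValueError("sd_multipliers must be increasing and positive")
    sigma = S[ref].std()
    if sigma == 0:
        raise ValueError("reference residual SD is zero; states are undefined")
    states = np.full(S.shape, int(CNVState.NEUTRAL), dtype=np.int8)
    states[S >= a * sigma] = int(CNVState.ONE_COPY_GAIN)
    states[S >= b * sigma] = int(CNVState.TWO_COPY_GAIN)
    states[S >= c * sigma] = int(CNVState.MULTI_COPY_GAIN)
    states[S <= -a * sigma] = int(CNVState.ONE_COPY_LOSS)
    states[S <= -b * sigma] = int(CNVState.COMPLETE_LOSS)
    return states


def cell_cnv_score(
    states: np.ndarray, weights: dict[CNVState, int] | None = None
) -> np.ndarray:
    """Per-cell CNV score: the sum of event weights over all genes."""
    table = weight_lookup(weights)
    return table[np.asarray(states, dtype=np.int64)].sum(axis=1)


def classify_cnv_level(
    tumor_scores: np.ndarray,
    reference_scores: np.ndarray,
) -> pd.Categorical:
    """Low/medium/high CNV degree anchored to the reference distribution.

    The baseline is the 95th percentile of reference scores; tumor cells at
    or below it are always "low". The remaining boundaries are the tertiles
    t1, t2 of the tumor excess (score - baseline) over all tumor cells:
    cells with excess in (0, t1] stay low, (t1, t2] are medium, and above
    t2 high. Anchoring the tertiles to the whole tumor population keeps the
    trisection meaningful when part of the cohort is near-diploid.
    Monotone in the score.
    """
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size < 10:
        raise ValueError("need >= 10 reference scores")
    scores = np.asarray(tumor_scores, dtype=float)
    baseline = np.percentile(ref, 95)
    excess = scores - baseline
    levels = np.full(scores.shape, "low", dtype=object)
    if not np.any(excess > 0):
        warnings.warn("no tumor cell exceeds the reference baseline; all low",
                      stacklevel=2)
    else:
        t1, t2 = np.quantile(excess, [1 / 3, 2 / 3])
        levels[(excess > t1) & (excess > 0)] = "medium"
        levels[(excess > t2) & (excess > 0)] = "high"
    return pd.Categorical(levels, categories=["low", "medium", "high"], ordered=True)


def arm_event_landscape(
    states: np.ndarray,
    annotation: pd.DataFrame,
    groups,
    weights: dict[CNVState, int] | None = None,
) -> pd.DataFrame:
    """Mean weighted gain/loss score per (group, arm).

    For each group of cells and each chromosome arm, the gain score is the
    per-cell sum of weights over gain-state genes of the arm, averaged over
    the group's cells; the loss score likewise over loss states. Gains and
    losses are never netted against each other.
    """
    S = np.asarray(states)
    if len(annotation) != S.shape[1]:
        raise ValueError("annotation rows must match state matrix columns")
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    if len(g) != S.shape[0]:
        raise ValueError("groups length must match state matrix rows")
    table = weight_lookup(weights)
    gain_w = np.where(np.isin(np.arange(len(CNVState)), [int(s) for s in GAIN_STATES]),
                      table, 0)
    loss_w = np.where(np.isin(np.arange(len(CNVState)), [int(s) for s in LOSS_STATES]),
                      table, 0)
    arm_col = annotation["arm"].to_numpy()
    rows = []
    for group in g.unique():
        cells = np.flatnonzero((g == group).to_numpy())
        sub = S[cells]
        per_gene_gain = gain_w[sub]  # cells x genes weights
        per_gene_loss = loss_w[sub]
        for arm in dict.fromkeys(arm_col):
            cols = arm_col == arm
            rows.append({"group": group, "arm": arm, "direction": "gain",
                         "score": float(per_gene_gain[:, cols].sum(axis=1).mean())})
            rows.append({"group": group, "arm": arm, "direction": "loss",
                         "score": float(per_gene_loss[:, cols].sum(axis=1).mean())})
    return pd.DataFrame(rows)
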