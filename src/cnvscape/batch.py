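"""The integration Local Inverse Simpson's Index (iLISI).

iLISI measures batch mixing in an embedding: for each cell, a Gaussian
kernel over its nearest neighbours is calibrated so that the weight
distribution has entropy log(perplexity); the batch-probability vector
p is the kernel-weighted batch composition of the neighbourhood, and the
cell's score is the inverse Simpson index 1 / sum_b p_b**2 — the effective
number of batches around the cell. A score of 1 means the neighbourhood is
a single batch (strong batch effect); B means perfect mixing of B batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["ILISIResult", "compute_ilisi"]


@dataclass
class ILISIResult:
    scores: pd.Series  # per-cell iLISI, in [1, B]
    perplexity: int
    n_batches: int

    @property
    def mean(self) -> float:
        return float(self.scores.mean())


def _calibrate_weights(d2: np.ndarray, log_perplexity: float,
                       n_iter: int = 50, tol: float = 1e-5) -> np.ndarray:
    """Gaussian weights over squared distances with entropy log(perplexity).

    Binary search on the precision beta, as in SNE perplexity calibration.
    """
    d2 = d2 - d2.min()  # shift-invariant; avoids underflow
    beta, beta_lo, beta_hi = 1.0, -np.inf, np.inf
    P = np.exp(-d2 * beta)
    for _ in range(n_iter):
        sumP = P.sum()
        if sumP == 0:
            # kernel collapsed: fall back to the single nearest neighbour
            P = np.zeros_like(d2)
            P[np.argmin(d2)] = 1.0
            return P
        H = np.log(sumP) + beta * (d2 * P).sum() / sumP
        diff = H - log_perplexity
        if abs(diff) < tol:
            break
        if diff > 0:  # entropy too high -> sharpen
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
        else:
            beta_hi = beta
            beta = beta / 2 if np.isinf(beta_lo) else (beta + beta_lo) / 2
        P = np.exp(-d2 * beta)
    sumP = P.sum()
    if sumP == 0:
        P = np.zeros_like(d2)
        P[np.argmin(d2)] = 1.0
        return P
    return P / sumP


def compute_ilisi(
    embedding: np.ndarray,
    batch_labels,
    perplexity: int = 30,
) -> ILISIResult:
    """Per-cell iLISI over the k = 3*perplexity nearest neighbours.

    Parameters
    ----------
    embedding
        cells x dims array (any embedding; distances are Euclidean).
    batch_labels
        One batch label per cell.
    perplexity
        Effective neighbourhood size for the kernel calibration.

    Returns per-cell scores in [1, B] where B is the number of batches.
    """
    X = np.asarray(embedding, dtype=float)
    labels = pd.Series(batch_labels).astype(str).reset_index(drop=True)
    n = X.shape[0]
    if len(labels) != n:
        raise ValueError("batch_labels length does not match embedding rows")
    batches = sorted(labels.unique())
    B = len(batches)
    index = (
        batch_labels.index
        if isinstance(batch_labels, pd.Series)
        else pd.RangeIndex(n)
    )
    if B == 1:
        warnings.warn("single batch: all iLISI scores are 1", stacklevel=2)
        return ILISIResult(pd.Series(np.ones(n), index=index), perplexity, 1)

    k = 3 * perplexity
    if k >= n:
        raise ValueError(f"k = 3*perplexity = {k} must be < n_cells = {n}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 cells")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    codes = pd.Categorical(labels, categories=batches).codes
    log_perp = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        w = _calibrate_weights(dist[i] ** 2, log_perp)
        p = np.bincount(codes[idx[i]], weights=w, minlength=B)
        p = p / p.sum()
        scores[i] = 1.0 / np.sum(p**2)
    scores = np.clip(scores, 1.0, B)
    return ILISIResult(pd.Series(scores, index=index), perplexity, B)
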