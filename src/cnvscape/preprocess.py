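"""QC filtering, normalisation, variable genes, PCA, significant-PC rule.

The QC thresholds follow the study conventions for droplet scRNA-seq:
cells are kept when they have at least ``min_umi`` UMIs, between
``min_genes`` and ``max_genes`` expressed genes, and at most
``max_mito_pct`` percent mitochondrial counts (mitochondrial genes are
recognised by an ``MT-`` symbol prefix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_metrics",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "run_pca",
    "select_significant_pcs",
]


@dataclass(frozen=True)
class QCThresholds:
    min_umi: int = 300
    max_mito_pct: float = 20.0
    min_genes: int = 200
    max_genes: int = 7500

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_pct <= 100.0:
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class QCReport:
    per_cell: pd.DataFrame  # n_umi, n_genes, mito_pct, pass, reasons
    n_before: int
    n_after: int

    @property
    def n_failed(self) -> int:
        return self.n_before - self.n_after


def _mito_mask(adata: AnnData) -> np.ndarray:
    symbols = (
        adata.var["symbol"] if "symbol" in adata.var else adata.var_names.to_series()
    )
    return symbols.astype(str).str.startswith("MT-").to_numpy()


def qc_metrics(adata: AnnData) -> pd.DataFrame:
    """Per-cell UMI total, expressed-gene count and mitochondrial percentage."""
    X = sp.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito = _mito_mask(adata)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(n_umi > 0, 100.0 * mito_counts / n_umi, 0.0)
    return pd.DataFrame(
        {"n_umi": n_umi, "n_genes": n_genes, "mito_pct": mito_pct},
        index=adata.obs_names,
    )


def qc_filter(
    adata: AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[AnnData, QCReport]:
    """Remove low-quality cells; the gene set and cell order are preserved.

    A cell passes when n_umi >= min_umi, min_genes <= n_genes <= max_genes
    and mito_pct <= max_mito_pct (a cell at exactly the mitochondrial
    threshold is retained).
    """
    metrics = qc_metrics(adata)
    t = thresholds
    checks = {
        "min_umi": metrics["n_umi"] >= t.min_umi,
        "min_genes": metrics["n_genes"] >= t.min_genes,
        "max_genes": metrics["n_genes"] <= t.max_genes,
        "max_mito_pct": metrics["mito_pct"] <= t.max_mito_pct,
    }
    ok = np.logical_and.reduce([c.to_numpy() for c in checks.values()])
    reasons = [
        ";".join(name for name, c in checks.items() if not c.iloc[i])
        for i in range(len(metrics))
    ]
    report = QCReport(
        per_cell=metrics.assign(passed=ok, reasons=reasons),
        n_before=adata.n_obs,
        n_after=int(ok.sum()),
    )
    return adata[ok].copy(), report


def normalize_log(X, scale_factor: float = 1e4, cell_ids=None) -> np.ndarray:
    """Library-size normalise and log-transform: ln(1 + sf * x / total).

    Operates per cell (row); raises on all-zero cells, naming the first
    offender.
    """
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.flatnonzero(totals == 0)[0])
        name = cell_ids[bad] if cell_ids is not None else bad
        raise ZeroDivisionError(f"cell {name!r} has zero total counts")
    return np.log1p(scale_factor * X / totals[:, None])


def select_hvg(X_norm: np.ndarray, gene_names, n_top: int = 3000, n_bins: int = 20):
    """Rank genes by variance-stabilised dispersion; return the top ``n_top``.

    The per-gene variance is compared to a mean/variance trend fitted by
    binned medians; genes are scored by the variance of their standardised
    expression clipped at sqrt(n_cells), so a handful of outlier cells
    cannot dominate. Constant genes score 0 and rank last. Deterministic:
    ties resolve by input gene order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    X = np.asarray(X_norm, dtype=float)
    n_cells, n_genes = X.shape
    gene_names = np.asarray(gene_names)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)

    # mean/variance trend by quantile-binned medians; keep >= 10 genes per
    # bin so a few genuinely variable genes cannot inflate their own trend
    expected = np.full(n_genes, np.nan)
    order = np.argsort(mean, kind="stable")
    n_bins_eff = int(np.clip(min(n_bins, n_genes // 10), 1, n_genes))
    bins = np.array_split(order, n_bins_eff)
    for idx in bins:
        if len(idx):
            expected[idx] = max(np.median(var[idx]), 1e-12)

    clip = np.sqrt(n_cells)
    Z = (X - mean) / np.sqrt(expected)
    np.clip(Z, -clip, clip, out=Z)
    score = Z.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    score[var == 0] = 0.0
    top = np.argsort(-score, kind="stable")[: min(n_top, n_genes)]
    return list(gene_names[top])


def run_pca(
    X_norm: np.ndarray,
    gene_subset=None,
    n_components: int = 50,
    clip: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled/centred PCA; returns (embedding, spectrum in % of variance).

    Genes are z-scored and clipped at ``+-clip`` before the decomposition;
    the spectrum is the percentage of the scaled matrix's total variance
    explained by each component.
    """
    X = np.asarray(X_norm, dtype=float)
    if gene_subset is not None:
        X = X[:, np.asarray(gene_subset)]
    n_cells, n_genes = X.shape
    if not 1 <= n_components <= min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} must be in [1, {min(n_cells, n_genes)}]"
        )
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip((X - X.mean(axis=0)) / sd, -clip, clip)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    embedding = pca.fit_transform(Z)
    spectrum = 100.0 * pca.explained_variance_ratio_
    return embedding, spectrum


def select_significant_pcs(
    spectrum,
    cum_threshold: float = 90.0,
    indiv_threshold: float = 5.0,
    diff_threshold: float = 0.1,
) -> int:
    """Number of significant PCs from the variance spectrum (percentages).

    Two stopping criteria are combined: c1 is the first component at which
    the cumulative contribution exceeds ``cum_threshold`` while the
    individual contribution is below ``indiv_threshold``; c2 is the last
    component whose drop to its successor exceeds ``diff_threshold``. The
    result is min over the criteria that fire, clamped to [1, len].
    """
    s = np.asarray(spectrum, dtype=float)
    if s.size == 0:
        raise ValueError("spectrum is empty")
    n = s.size
    cum = np.cumsum(s)
    candidates = []
    c1_hits = np.flatnonzero((cum > cum_threshold) & (s < indiv_threshold))
    if c1_hits.size:
        candidates.append(int(c1_hits[0]) + 1)
    if n > 1:
        drops = np.flatnonzero((s[:-1] - s[1:]) > diff_threshold)
        if drops.size:
            candidates.append(int(drops[-1]) + 1)
    k = min(candidates) if candidates else n
    return int(np.clip(k, 1, n))
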