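"""Cell/gene quality control, LogNormalize, and VST highly-variable genes.

QC keeps cells with >= 500 UMIs, >= 250 detected genes and a
log10(genes)/log10(UMI) complexity ratio above 0.85, then keeps genes
detected in at least 10 of the surviving cells.  Normalization is the
LogNormalize transform ln(1 + count / cell_total * scale_factor).  HVG
selection standardizes per-gene variance against a loess mean-variance
trend on raw counts, clipping standardized values at sqrt(n_cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("nephrosig")

__all__ = ["QCThresholds", "qc_filter", "log_normalize", "select_hvg_vst", "scale_genes"]


@dataclass(frozen=True)
class QCThresholds:
    min_umi: int = 500
    min_genes_per_cell: int = 250
    min_log10_genes_per_umi: float = 0.85
    min_cells_per_gene: int = 10
    scale_factor: float = 10_000.0
    n_hvg: int = 2_000

    def __post_init__(self) -> None:
        if min(self.min_umi, self.min_genes_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def _counts(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))


def qc_filter(adata: AnnData, thresholds: QCThresholds = QCThresholds()) -> AnnData:
    """Apply the three cell filters, then the gene detection filter.

    Cells are kept when UMI >= min_umi, detected genes >= min_genes_per_cell
    and log10(genes)/log10(UMI) > min_log10_genes_per_umi (strict).  Genes
    are then kept when detected in >= min_cells_per_gene surviving cells.
    Row/column order is preserved; a step-by-step report is attached at
    ``.uns['qc_report']``.
    """
    X = _counts(adata)
    n_cells0, n_genes0 = X.shape
    umi = np.asarray(X.sum(axis=1)).ravel()
    genes_det = np.asarray((X > 0).sum(axis=1)).ravel()

    keep_umi = umi >= thresholds.min_umi
    keep_genes = genes_det >= thresholds.min_genes_per_cell
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (umi > 1) & (genes_det > 0), np.log10(genes_det) / np.log10(umi), 0.0
        )
    keep_ratio = ratio > thresholds.min_log10_genes_per_umi
    keep_cell = keep_umi & keep_genes & keep_ratio
    if not keep_cell.any():
        raise ValueError("all cells removed by QC filtering")

    sub = adata[keep_cell].copy()
    Xc = _counts(sub)
    cells_per_gene = np.asarray((Xc > 0).sum(axis=0)).ravel()
    keep_gene = cells_per_gene >= thresholds.min_cells_per_gene
    out = sub[:, keep_gene].copy()

    report = pd.DataFrame(
        [
            ("umi_filter", n_cells0, int(keep_umi.sum()), n_genes0, n_genes0),
            ("gene_detection_filter", n_cells0, int(keep_genes.sum()), n_genes0, n_genes0),
            ("complexity_filter", n_cells0, int(keep_ratio.sum()), n_genes0, n_genes0),
            ("combined_cell_filters", n_cells0, int(keep_cell.sum()), n_genes0, n_genes0),
            ("gene_filter", int(keep_cell.sum()), int(keep_cell.sum()),
             n_genes0, int(keep_gene.sum())),
        ],
        columns=["step", "cells_before", "cells_after", "genes_before", "genes_after"],
    )
    out.uns["qc_report"] = report
    logger.info(
        "qc: %d/%d cells, %d/%d genes retained",
        out.n_obs, n_cells0, out.n_vars, n_genes0,
    )
    return out


def log_normalize(adata: AnnData, scale_factor: float = 10_000.0) -> AnnData:
    """LogNormalize: entry -> ln(1 + count / cell_total * scale_factor)."""
    X = _counts(adata).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cell with zero total count cannot be normalized")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    X = sp.diags(scale_factor / totals) @ X
    X.data = np.log1p(X.data)
    out.X = X.tocsr()
    out.uns["layer"] = "lognorm"
    out.uns["scale_factor"] = scale_factor
    return out


def select_hvg_vst(adata: AnnData, n_hvg: int = 2_000, *, span: float = 0.3) -> list[str]:
    """Rank genes by standardized variance under a VST mean-variance trend.

    Fits a loess of log10(variance) on log10(mean) over genes with positive
    variance (raw counts), standardizes each count against the fitted
    expected sd, clips standardized values at sqrt(n_cells), and returns the
    ``n_hvg`` gene names with the largest variance of the clipped values.
    """
    if n_hvg > adata.n_vars:
        raise ValueError("n_hvg exceeds the number of genes")
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = X.tocsc() if sp.issparse(X) else sp.csc_matrix(np.asarray(X))
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= n / max(n - 1, 1)

    std_var = np.zeros(X.shape[1])
    pos = var > 0
    if pos.any():
        fitted = lowess(
            np.log10(var[pos]), np.log10(mean[pos]), frac=span,
            return_sorted=False,
        )
        exp_sd = np.sqrt(10.0**fitted)
        clip = np.sqrt(n)
        # variance of clipped standardized counts, using sparsity:
        # zeros standardize to -mean/sd (never clipped upward).
        pos_idx = np.flatnonzero(pos)
        for j, sd, m in zip(pos_idx, exp_sd, mean[pos]):
            col = X.data[X.indptr[j] : X.indptr[j + 1]]
            z = np.minimum((col - m) / sd, clip)
            n_zero = n - col.size
            zsum = z.sum() + n_zero * (-m / sd)
            zsq = (z**2).sum() + n_zero * (m / sd) ** 2
            std_var[j] = (zsq - zsum**2 / n) / max(n - 1, 1)
    order = np.argsort(-std_var, kind="stable")
    return [adata.var_names[i] for i in order[:n_hvg]]


def scale_genes(adata: AnnData, genes: list[str] | None = None, max_value: float = 10.0) -> AnnData:
    """Per-gene z-scoring of the current layer (optional downstream consumer)."""
    sub = adata[:, genes].copy() if genes is not None else adata.copy()
    X = np.asarray(sub.X.todense()) if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    sub.X = np.clip((X - mu) / sd, -max_value, max_value)
    sub.uns["layer"] = "scaled"
    return sub
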