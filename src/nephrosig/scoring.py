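"""Per-cell composite drug scores from target-gene expression.

A drug's score in a cell is the arithmetic mean of the cell's (log-
normalized) expression over the drug's measured target genes — the plain
drug2cell-style composite.  Scores are then natural-log transformed with a
small pseudocount, and aggregated to cell-type level as the mean logged
score over the cells of each type; the logged cell-by-drug matrix is what
all downstream analyses consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .synthetic import DrugTargetDB

logger = logging.getLogger("nephrosig")

__all__ = [
    "DrugScoreMatrix",
    "build_target_matrix",
    "score_cells",
    "log_transform_scores",
    "aggregate_by_cell_type",
    "LOG_PSEUDOCOUNT",
]

#: Pseudocount added before the natural-log transform of raw scores.
LOG_PSEUDOCOUNT = 1e-9


@dataclass
class DrugScoreMatrix:
    """Cells x drugs composite scores (raw, and optionally logged)."""

    raw: np.ndarray                 # cells x drugs, nonnegative
    drug_ids: list[str]
    nephrotoxic: np.ndarray         # bool per drug
    obs: pd.DataFrame               # per-cell metadata (cell types, donor)
    logged: np.ndarray | None = None
    log_pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.raw.shape != (len(self.obs), len(self.drug_ids)):
            raise ValueError("score matrix shape inconsistent with metadata")


def build_target_matrix(
    db: DrugTargetDB, gene_universe: list[str]
) -> tuple[sp.csr_matrix, list[str], np.ndarray]:
    """Binary drug-by-gene target matrix restricted to the measured universe.

    Drugs none of whose targets are in the universe are excluded with a
    warning.  Returns ``(matrix, kept_drug_ids, kept_nephrotoxic_flags)``.
    """
    if not gene_universe:
        raise ValueError("gene universe is empty")
    if not db.records:
        raise ValueError("drug database is empty")
    gene_idx = {g: i for i, g in enumerate(gene_universe)}
    rows, cols = [], []
    kept_ids, kept_tox = [], []
    n_excluded = 0
    for rec in db.records:
        hit = [gene_idx[g] for g in rec.target_genes if g in gene_idx]
        if not hit:
            n_excluded += 1
            logger.warning(
                "scoring: drug %s has no measured targets; excluded", rec.drug_id
            )
            continue
        r = len(kept_ids)
        rows.extend([r] * len(hit))
        cols.extend(hit)
        kept_ids.append(rec.drug_id)
        kept_tox.append(rec.nephrotoxic)
    if not kept_ids:
        raise ValueError("no drug has measured targets in the universe")
    if n_excluded:
        logger.warning("scoring: excluded %d/%d drugs", n_excluded, len(db.records))
    T = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(kept_ids), len(gene_universe))
    )
    return T, kept_ids, np.asarray(kept_tox, dtype=bool)


def score_cells(
    adata: AnnData, targets: sp.spmatrix, drug_ids: list[str], nephrotoxic: np.ndarray
) -> DrugScoreMatrix:
    """score(cell, drug) = mean expression over the drug's target genes."""
    if targets.shape[1] != adata.n_vars:
        raise ValueError(
            f"target matrix has {targets.shape[1]} genes, expression has {adata.n_vars}"
        )
    n_targets = np.asarray(targets.sum(axis=1)).ravel()
    if np.any(n_targets == 0):
        raise ValueError("target matrix contains drugs with zero targets")
    X = adata.X
    sums = X @ targets.T.tocsc()
    sums = np.asarray(sums.todense()) if sp.issparse(sums) else np.asarray(sums)
    raw = sums / n_targets[None, :]
    return DrugScoreMatrix(
        raw=raw,
        drug_ids=list(drug_ids),
        nephrotoxic=np.asarray(nephrotoxic, dtype=bool),
        obs=adata.obs.copy(),
    )


def log_transform_scores(
    scores: DrugScoreMatrix, pseudocount: float = LOG_PSEUDOCOUNT
) -> DrugScoreMatrix:
    """Natural-log transform: logged = ln(raw + pseudocount)."""
    if np.any(scores.raw < 0):
        raise ValueError("raw scores must be nonnegative")
    return DrugScoreMatrix(
        raw=scores.raw,
        drug_ids=scores.drug_ids,
        nephrotoxic=scores.nephrotoxic,
        obs=scores.obs,
        logged=np.log(scores.raw + pseudocount),
        log_pseudocount=pseudocount,
    )


def aggregate_by_cell_type(
    scores: DrugScoreMatrix, level: str = "detailed32"
) -> pd.DataFrame:
    """Mean logged score per (drug, cell type).

    Returns a long-format table with columns drug_id, cell_type, level,
    mean_log_score, nephrotoxic — one row per (drug, type) pair.
    """
    if scores.logged is None:
        raise ValueError("scores must be log-transformed before aggregation")
    col = "abstract_type" if level == "abstract4" else "detailed_type"
    if col not in scores.obs:
        raise ValueError(f"cell annotations lack {col!r}")
    types = scores.obs[col].astype(str).to_numpy()
    rows = []
    for t in sorted(set(types)):
        mean_t = scores.logged[types == t].mean(axis=0)
        for j, d in enumerate(scores.drug_ids):
            rows.append((d, t, level, mean_t[j], bool(scores.nephrotoxic[j])))
    return pd.DataFrame(
        rows, columns=["drug_id", "cell_type", "level", "mean_log_score", "nephrotoxic"]
    )
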