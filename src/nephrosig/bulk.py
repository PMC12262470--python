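"""Bulk signature arm: replicate collapsing and toxic vs non-toxic DE.

Profiles are samples x genes signature values (z-score-like, may be
negative), each sample belonging to one drug.  Replicates of a drug are
collapsed by per-gene averaging; differential expression between toxic and
non-toxic profiles uses a per-gene Welch t-test with BH FDR.  The default
gene-selection rule is p < p_cut AND |log2FC| <= lfc_cut; the conventional
>= direction is available via ``lfc_direction='ge'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import bh_fdr

__all__ = ["BulkProfileSet", "DEResult", "collapse_replicates", "differential_expression"]


@dataclass
class BulkProfileSet:
    """Samples x genes signatures plus per-sample drug and toxicity labels."""

    profiles: pd.DataFrame       # samples x genes
    meta: pd.DataFrame           # index = samples; columns drug_id, nephrotoxic

    def __post_init__(self) -> None:
        if not self.profiles.index.equals(self.meta.index):
            raise ValueError("profiles and metadata indices differ")
        if not {"drug_id", "nephrotoxic"} <= set(self.meta.columns):
            raise ValueError("metadata must carry drug_id and nephrotoxic")


@dataclass(frozen=True)
class DEResult:
    gene: str
    p_value: float
    log2_fold_change: float
    mean_toxic: float
    mean_nontoxic: float
    fdr: float


def collapse_replicates(bulk: BulkProfileSet) -> BulkProfileSet:
    """One profile per drug: the per-gene mean over the drug's replicates."""
    if bulk.profiles.empty:
        raise ValueError("empty profile set")
    grouped = bulk.profiles.groupby(bulk.meta["drug_id"], observed=True).mean()
    tox = bulk.meta.drop_duplicates("drug_id").set_index("drug_id")["nephrotoxic"]
    meta = pd.DataFrame(
        {"drug_id": grouped.index, "nephrotoxic": tox.reindex(grouped.index).astype(bool)},
        index=grouped.index,
    )
    return BulkProfileSet(profiles=grouped, meta=meta)


def differential_expression(
    bulk: BulkProfileSet,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    *,
    lfc_direction: str = "le",
) -> tuple[list[DEResult], list[str]]:
    """Per-gene Welch t-test of toxic vs non-toxic samples.

    log2FC is the difference of group means (profiles are already on a
    log-like signature scale).  Returns all per-gene results plus the genes
    passing p < p_cut and |log2FC| <= lfc_cut (or >= with
    ``lfc_direction='ge'``), sorted by p ascending.
    """
    if lfc_direction not in ("le", "ge"):
        raise ValueError("lfc_direction must be 'le' or 'ge'")
    toxic_mask = bulk.meta["nephrotoxic"].to_numpy(dtype=bool)
    if toxic_mask.sum() < 2 or (~toxic_mask).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    A = bulk.profiles.to_numpy(dtype=float)[toxic_mask]
    B = bulk.profiles.to_numpy(dtype=float)[~toxic_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    mt, mn = A.mean(axis=0), B.mean(axis=0)
    lfc = mt - mn
    fdr = bh_fdr(p)
    results = [
        DEResult(
            gene=g,
            p_value=float(p[j]),
            log2_fold_change=float(lfc[j]),
            mean_toxic=float(mt[j]),
            mean_nontoxic=float(mn[j]),
            fdr=float(fdr[j]),
        )
        for j, g in enumerate(bulk.profiles.columns)
    ]
    results.sort(key=lambda r: r.p_value)
    if lfc_direction == "le":
        selected = [r.gene for r in results if r.p_value < p_cut and abs(r.log2_fold_change) <= lfc_cut]
    else:
        selected = [r.gene for r in results if r.p_value < p_cut and abs(r.log2_fold_change) >= lfc_cut]
    return results, selected


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    """Long-format DE table (gene, pvalue, log2FoldChange, means, FDR)."""
    return pd.DataFrame([r.__dict__ for r in results])
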