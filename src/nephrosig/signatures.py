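"""Per-cell-type toxic vs non-toxic drug-score comparisons.

For each cell type, the unit of observation is the drug: its mean logged
score over the cells of that type.  A Welch two-sample t-test compares
nephrotoxic against non-nephrotoxic drugs; the log fold change is the
difference of group means on the natural-log scale, so fold change =
exp(logFC) and the 95% CI is the exponentiated t-based CI of the mean
difference.  P-values are Benjamini-Hochberg corrected across the cell
types of one abstraction level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SignatureRow", "compare_groups", "bh_fdr", "fold_change_from_log"]


@dataclass(frozen=True)
class SignatureRow:
    cell_type: str
    level: str
    t_statistic: float
    log_fold_change: float
    fold_change: float
    ci_lower_95: float
    ci_upper_95: float
    p_value: float
    corrected_p: float
    n_toxic: int
    n_nontoxic: int


def fold_change_from_log(log_fold_change: float) -> float:
    """Fold change under the natural-log convention: FC = e^logFC."""
    return float(np.exp(log_fold_change))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(table: pd.DataFrame) -> list[SignatureRow]:
    """Welch t-tests of toxic vs non-toxic mean drug scores, per cell type.

    ``table`` is the long-format cell-type score table (columns drug_id,
    cell_type, level, mean_log_score, nephrotoxic).  Rows are returned
    sorted by corrected p ascending, ties broken by |t| descending.
    """
    required = {"drug_id", "cell_type", "level", "mean_log_score", "nephrotoxic"}
    if not required <= set(table.columns):
        raise ValueError(f"score table missing columns {required - set(table.columns)}")
    rows = []
    for (ct, level), grp in table.groupby(["cell_type", "level"], observed=True):
        tox = grp.loc[grp["nephrotoxic"].astype(bool), "mean_log_score"].to_numpy()
        non = grp.loc[~grp["nephrotoxic"].astype(bool), "mean_log_score"].to_numpy()
        if len(tox) < 2 or len(non) < 2:
            raise ValueError(f"degenerate group for cell type {ct!r}")
        res = stats.ttest_ind(tox, non, equal_var=False)
        ci = res.confidence_interval(confidence_level=0.95)
        lfc = float(tox.mean() - non.mean())
        rows.append(
            SignatureRow(
                cell_type=str(ct),
                level=str(level),
                t_statistic=float(res.statistic),
                log_fold_change=lfc,
                fold_change=fold_change_from_log(lfc),
                ci_lower_95=float(np.exp(ci.low)),
                ci_upper_95=float(np.exp(ci.high)),
                p_value=float(res.pvalue),
                corrected_p=np.nan,  # filled below, within level
                n_toxic=len(tox),
                n_nontoxic=len(non),
            )
        )
    out: list[SignatureRow] = []
    for level in sorted({r.level for r in rows}):
        level_rows = [r for r in rows if r.level == level]
        adj = bh_fdr([r.p_value for r in level_rows])
        for r, q in zip(level_rows, adj):
            out.append(
                SignatureRow(
                    **{**r.__dict__, "corrected_p": float(max(q, r.p_value))}
                )
            )
    out.sort(key=lambda r: (r.corrected_p, -abs(r.t_statistic)))
    return out


def signature_frame(rows: list[SignatureRow]) -> pd.DataFrame:
    """Table mirroring the published per-cell-type signature columns."""
    return pd.DataFrame([r.__dict__ for r in rows])
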