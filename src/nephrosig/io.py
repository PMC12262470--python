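"""MatrixMarket / TSV / CSV exchange formats.

A matrix directory holds ``matrix.mtx`` (genes x cells, CellRanger
orientation), ``features.tsv``, ``barcodes.tsv`` and ``annotations.tsv``
(barcode, detailed_type, abstract_type, donor).  Drug databases are CSV
with semicolon-joined target genes.  Round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .synthetic import DrugTargetDB

__all__ = ["read_matrix", "write_matrix", "read_drug_db", "write_drug_db"]

ANNOTATION_COLUMNS = ("detailed_type", "abstract_type", "donor")


def write_matrix(adata: AnnData, out_dir: str | Path) -> Path:
    """Write a cell matrix as MTX + features/barcodes/annotations TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    mmwrite(str(out / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    ann = adata.obs.reset_index().rename(columns={"index": "barcode"})
    ann = ann[["barcode", *[c for c in ANNOTATION_COLUMNS if c in ann.columns]]]
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
    return out


def read_matrix(in_dir: str | Path) -> AnnData:
    """Read a matrix directory back into an AnnData (inverse of write_matrix)."""
    d = Path(in_dir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "annotations.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing {name} in {d}")
    X = sp.csr_matrix(mmread(str(d / "matrix.mtx"))).T.tocsr()
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if X.shape[1] != len(genes):
        raise ValueError(
            f"features.tsv lists {len(genes)} genes but matrix.mtx has {X.shape[1]}"
        )
    if X.shape[0] != len(barcodes):
        raise ValueError(
            f"barcodes.tsv lists {len(barcodes)} cells but matrix.mtx has {X.shape[0]}"
        )
    ann = pd.read_csv(d / "annotations.tsv", sep="\t", dtype=str)
    ann = ann.set_index("barcode")
    missing = set(barcodes) - set(ann.index)
    if missing or ann.isna().any().any():
        bad = sorted(missing) or sorted(ann.index[ann.isna().any(axis=1)])
        raise ValueError(f"annotations.tsv incomplete for barcodes: {bad[:10]}")
    obs = ann.reindex(barcodes)
    obs.index.name = None
    adata = AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.uns["layer"] = "counts"
    return adata


def write_drug_db(db: DrugTargetDB, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    db.to_frame().to_csv(path, index=False)
    return path


def read_drug_db(path: str | Path) -> DrugTargetDB:
    return DrugTargetDB.from_frame(pd.read_csv(path))
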