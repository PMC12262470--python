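"""Shared fixtures: small synthetic datasets kept fast enough for CI."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import nephrosig as ns

# Relaxed QC for small matrices (default thresholds assume ~20k-gene panels).
SMALL_QC = ns.QCThresholds(
    min_umi=30, min_genes_per_cell=20, min_log10_genes_per_umi=0.5,
    min_cells_per_gene=3,
)


@pytest.fixture(scope="session")
def abstract_specs():
    return ns.abstract_cell_type_specs(400)


@pytest.fixture(scope="session")
def abstract_matrix(abstract_specs):
    cfg = ns.SyntheticConfig(
        n_cells=2000, n_genes=400, n_donors=6, target_sparsity=0.85, seed=101,
        cell_type_specs=abstract_specs,
    )
    return ns.generate_cell_matrix(cfg)


@pytest.fixture(scope="session")
def abstract_lognorm(abstract_matrix):
    return ns.log_normalize(ns.qc_filter(abstract_matrix, SMALL_QC))


@pytest.fixture(scope="session")
def detailed_specs():
    return ns.detailed_cell_type_specs(600)


@pytest.fixture(scope="session")
def detailed_lognorm(detailed_specs):
    cfg = ns.SyntheticConfig(
        n_cells=3000, n_genes=600, n_donors=6, target_sparsity=0.85, seed=202,
        cell_type_specs=detailed_specs,
    )
    adata = ns.generate_cell_matrix(cfg)
    return ns.log_normalize(ns.qc_filter(adata, SMALL_QC))


@pytest.fixture(scope="session")
def small_db(detailed_specs):
    signal = ns.SignalSpec(frozenset({"Indistinct intercalated cell"}), 0.5)
    return ns.generate_drug_db(
        40, 120, signal, ns.gene_universe(600), seed=7, cell_type_specs=detailed_specs
    )


@pytest.fixture(scope="session")
def score_table(detailed_lognorm, small_db):
    T, ids, tox = ns.build_target_matrix(small_db, list(detailed_lognorm.var_names))
    logged = ns.log_transform_scores(ns.score_cells(detailed_lognorm, T, ids, tox))
    return pd.concat(
        [
            ns.aggregate_by_cell_type(logged, "detailed32"),
            ns.aggregate_by_cell_type(logged, "abstract4"),
        ],
        ignore_index=True,
    )


def make_adata(X, detailed, abstract=None, donors=None):
    """Hand-built annotated matrix for targeted unit tests."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    obs = pd.DataFrame(
        {
            "detailed_type": detailed,
            "abstract_type": abstract if abstract is not None else detailed,
            "donor": donors if donors is not None else ["D1"] * n,
        },
        index=[f"C{i}" for i in range(n)],
    )
    var = pd.DataFrame(index=[f"G{j}" for j in range(X.shape[1])])
    return AnnData(X=X, obs=obs, var=var)
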