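"""Generator contracts: prevalences, sparsity, determinism, drug databases."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import nephrosig as ns


def _single_type_config(n_cells=50, n_genes=30, seed=0):
    spec = ns.CellTypeSpec(
        name="OnlyType",
        abstract_parent="Nephron",
        prevalence=1.0,
        marker_genes=frozenset(ns.gene_universe(n_genes)[:3]),
        base_mean=np.full(n_genes, 0.5),
        dispersion=np.full(n_genes, 0.4),
    )
    return ns.SyntheticConfig(
        n_cells=n_cells, n_genes=n_genes, n_donors=2, target_sparsity=0.7,
        seed=seed, cell_type_specs=[spec],
    )


def test_degenerate_prevalence_assigns_all_cells_to_single_type():
    adata = ns.generate_cell_matrix(_single_type_config())
    assert set(adata.obs["detailed_type"]) == {"OnlyType"}
    assert set(adata.obs["abstract_type"]) == {"Nephron"}


def test_nephron_fraction_within_binomial_bounds():
    """A 10,000-cell draw at the published prevalences recovers ~82.4% Nephron."""
    cfg = ns.SyntheticConfig(
        n_cells=10_000, n_genes=60, n_donors=4, target_sparsity=0.8, seed=3,
        cell_type_specs=ns.abstract_cell_type_specs(60),
    )
    adata = ns.generate_cell_matrix(cfg)
    frac = (adata.obs["abstract_type"] == "Nephron").mean()
    p = 0.824 / 0.999
    bound = stats.norm.ppf(0.995) * np.sqrt(p * (1 - p) / 10_000)
    assert abs(frac - p) < bound


def test_same_seed_identical_different_seed_differs(abstract_specs):
    mk = lambda seed: ns.generate_cell_matrix(
        ns.SyntheticConfig(
            n_cells=300, n_genes=400, n_donors=3, target_sparsity=0.85,
            seed=seed, cell_type_specs=abstract_specs,
        )
    )
    a, b, c = mk(9), mk(9), mk(10)
    assert (a.X != b.X).nnz == 0
    assert a.obs.equals(b.obs)
    assert (a.X != c.X).nnz > 0


def test_prevalence_convergence_at_large_n():
    cfg = ns.SyntheticConfig(
        n_cells=100_000, n_genes=40, n_donors=4, target_sparsity=0.8, seed=5,
        cell_type_specs=ns.abstract_cell_type_specs(40),
    )
    adata = ns.generate_cell_matrix(cfg)
    realized = adata.obs["abstract_type"].value_counts(normalize=True)
    for spec in cfg.cell_type_specs:
        assert abs(realized.get(spec.name, 0.0) - spec.prevalence) < 0.01


@pytest.mark.parametrize("target", [0.75, 0.9])
def test_realized_sparsity_tracks_target(abstract_specs, target):
    cfg = ns.SyntheticConfig(
        n_cells=800, n_genes=400, n_donors=3, target_sparsity=target, seed=11,
        cell_type_specs=abstract_specs,
    )
    adata = ns.generate_cell_matrix(cfg)
    assert abs(adata.uns["zero_fraction"] - target) < 0.05


def test_generator_input_validation(abstract_specs):
    with pytest.raises(ValueError, match="too few cells"):
        ns.generate_cell_matrix(
            ns.SyntheticConfig(
                n_cells=2, n_genes=400, n_donors=2, target_sparsity=0.8, seed=0,
                cell_type_specs=ns.abstract_cell_type_specs(400),
            )
        )
    bad = _single_type_config()
    spec = bad.cell_type_specs[0]
    half = ns.CellTypeSpec(
        name=spec.name, abstract_parent=spec.abstract_parent, prevalence=0.5,
        marker_genes=spec.marker_genes, base_mean=spec.base_mean,
        dispersion=spec.dispersion,
    )
    bad.cell_type_specs = [half]
    with pytest.raises(ValueError, match="prevalences sum"):
        ns.generate_cell_matrix(bad)


# --- drug databases ---------------------------------------------------------

def test_drug_db_class_counts():
    """The curated database ratio: 215 nephrotoxic + 641 non-nephrotoxic."""
    db = ns.generate_drug_db(
        215, 641, ns.SignalSpec(), ns.gene_universe(500), seed=1
    )
    assert len(db) == 856
    assert db.n_toxic == 215
    assert len({r.drug_id for r in db.records}) == 856


def test_full_enrichment_confines_toxic_targets_to_markers(detailed_specs):
    signal = ns.SignalSpec(frozenset({"Podocyte"}), 1.0)
    db = ns.generate_drug_db(
        20, 20, signal, ns.gene_universe(600), seed=2, cell_type_specs=detailed_specs
    )
    markers = next(s for s in detailed_specs if s.name == "Podocyte").marker_genes
    for rec in db.records:
        if rec.nephrotoxic:
            assert rec.target_genes <= markers


def test_null_database_targets_independent_of_label(detailed_specs):
    """Enrichment 0: marker membership of targets carries no label signal."""
    markers = set().union(*(s.marker_genes for s in detailed_specs))
    counts = np.zeros((2, 2))
    for seed in range(50):
        db = ns.generate_drug_db(
            20, 60, ns.SignalSpec(), ns.gene_universe(600), seed=seed
        )
        for rec in db.records:
            hit = int(bool(rec.target_genes & markers))
            counts[int(rec.nephrotoxic), hit] += 1
    _, p, _, _ = stats.chi2_contingency(counts)
    assert p > 0.01


def test_enrichment_without_markers_errors():
    with pytest.raises(ValueError):
        ns.generate_drug_db(
            5, 5, ns.SignalSpec(frozenset({"Podocyte"}), 0.5),
            ns.gene_universe(100), seed=0, cell_type_specs=[],
        )
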