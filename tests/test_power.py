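"""Subsampling, drug-effect application, pseudo-bulking, and power."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import nephrosig as ns
from conftest import make_adata


def test_subsample_fraction_one_is_identity(abstract_lognorm):
    out = ns.subsample_preserving_prevalence(abstract_lognorm, 1.0, seed=0)
    assert out.shape == abstract_lognorm.shape
    assert list(out.obs_names) == list(abstract_lognorm.obs_names)


def test_subsample_exact_per_type_counts():
    X = np.ones((1250, 5))
    types = ["A"] * 1000 + ["B"] * 250
    adata = make_adata(X, types)
    out = ns.subsample_preserving_prevalence(adata, 0.10, seed=1, level="detailed32")
    counts = out.obs["detailed_type"].value_counts()
    assert counts["A"] == 100 and counts["B"] == 25


def test_subsample_seeds_change_members_not_counts(abstract_lognorm):
    a = ns.subsample_preserving_prevalence(abstract_lognorm, 0.2, seed=1, level="abstract4")
    b = ns.subsample_preserving_prevalence(abstract_lognorm, 0.2, seed=2, level="abstract4")
    ca = a.obs["abstract_type"].value_counts()
    cb = b.obs["abstract_type"].value_counts()
    assert ca.equals(cb)
    assert set(a.obs_names) != set(b.obs_names)


def test_apply_drug_effect_zero_effect_is_identity(abstract_lognorm):
    out = ns.apply_drug_effect(abstract_lognorm, "Nephron", 0.0, 0.8, seed=3)
    assert np.allclose(
        np.asarray(out.X.todense()), np.asarray(abstract_lognorm.X.todense())
    )


def test_apply_drug_effect_multiplier_and_isolation():
    X = np.full((10, 3), 2.0)
    types = ["A"] * 6 + ["B"] * 4
    adata = make_adata(X, types)
    out = ns.apply_drug_effect(adata, "A", 10.0, 1.0, seed=0)
    V = np.asarray(out.X)
    assert np.allclose(V[:6], 22.0)          # baseline x (1 + 10)
    assert np.allclose(V[6:], 2.0)           # other types untouched
    # rate 1, effect 1: exact doubling of the type
    out2 = ns.apply_drug_effect(adata, "B", 1.0, 1.0, seed=0)
    assert np.allclose(np.asarray(out2.X)[6:], 4.0)
    assert np.allclose(np.asarray(out2.X)[:6], 2.0)
    # original not mutated; zeros conserved
    assert np.allclose(np.asarray(adata.X), 2.0)
    adata.X[0, 0] = 0.0
    out3 = ns.apply_drug_effect(adata, "A", 5.0, 1.0, seed=0)
    assert np.asarray(out3.X)[0, 0] == 0.0


def test_apply_drug_effect_unknown_type_errors(abstract_lognorm):
    with pytest.raises(ValueError, match="unknown cell type"):
        ns.apply_drug_effect(abstract_lognorm, "Hepatocyte", 1.0, 0.8, seed=0)


def test_pseudo_bulk_means():
    X = np.array([[1.0, 5.0], [3.0, 5.0]])
    adata = make_adata(X, ["A", "B"], donors=["D1", "D1"])
    prof = ns.pseudo_bulk(adata, "none")
    assert prof.iloc[0, 0] == 2.0 and prof.iloc[0, 1] == 5.0
    # identical cells: pseudo-bulk equals any single cell
    same = make_adata(np.tile([2.0, 7.0], (5, 1)), ["A"] * 5)
    assert np.allclose(ns.pseudo_bulk(same, "none").to_numpy(), [2.0, 7.0])


def test_pseudo_bulk_dilutes_rare_subtype_signal():
    """A 2.6%-prevalence subtype at value 10 averages to 0.26 in pseudo-bulk."""
    n = 1000
    X = np.zeros((n, 1))
    X[:26, 0] = 10.0
    types = ["Rare"] * 26 + ["Common"] * (n - 26)
    prof = ns.pseudo_bulk(make_adata(X, types), "none")
    assert prof.iloc[0, 0] == pytest.approx(0.26)


def test_power_toy_one_of_three_genes_detectable():
    """2 donors per arm, one strongly shifted gene, two flat -> power 1/3."""
    rng = np.random.default_rng(0)
    n = 8
    X = np.zeros((n, 3))
    X[:, 0] = 1.0 + rng.normal(0, 1e-6, size=n)
    donors = ["D1", "D2"] * 4
    adata = make_adata(X, ["A"] * n, donors=donors)
    grid = ns.SimulationGrid(
        effect_sizes=[10.0], response_rates=[1.0], subsample_fraction=1.0,
        n_replicate_runs=1, seed=0,
    )
    res = ns.run_power_grid(adata, grid, "pseudo_bulk")
    assert len(res) == 1
    assert res[0].power == pytest.approx(1 / 3)


def test_power_null_calibration(abstract_lognorm):
    grid = ns.SimulationGrid(
        effect_sizes=[0.0], response_rates=[0.8], subsample_fraction=0.5,
        n_replicate_runs=2, seed=0,
    )
    res = ns.run_power_grid(abstract_lognorm, grid, "pseudo_bulk",
                            cell_types=["Nephron"])
    assert res[0].power <= 0.001


def test_power_nondecreasing_in_effect_size(abstract_lognorm):
    grid = ns.SimulationGrid(
        effect_sizes=[0.1, 1.0, 10.0], response_rates=[0.8],
        subsample_fraction=0.5, n_replicate_runs=3, seed=4,
    )
    res = ns.run_power_grid(abstract_lognorm, grid, "cell_level",
                            cell_types=["Nephron"])
    powers = [r.power for r in sorted(res, key=lambda r: r.effect_size)]
    assert powers[-1] > 0  # signal detectable at the top of the grid
    rho = stats.spearmanr([r.effect_size for r in res], [r.power for r in res]).statistic
    assert np.isnan(rho) or rho >= 0


def test_power_invariant_to_cell_and_gene_order(abstract_lognorm):
    grid = ns.SimulationGrid(
        effect_sizes=[10.0], response_rates=[0.8], subsample_fraction=0.5,
        n_replicate_runs=2, seed=9,
    )
    base = ns.run_power_grid(abstract_lognorm, grid, "pseudo_bulk",
                             cell_types=["Nephron"])[0].power
    rng = np.random.default_rng(1)
    perm_genes = rng.permutation(abstract_lognorm.n_vars)
    shuffled = abstract_lognorm[:, perm_genes].copy()
    perm = ns.run_power_grid(shuffled, grid, "pseudo_bulk",
                             cell_types=["Nephron"])[0].power
    assert perm == pytest.approx(base, abs=0.02)


def test_power_requires_donor_replicates():
    adata = make_adata(np.ones((6, 3)), ["A"] * 6, donors=["D1"] * 6)
    grid = ns.SimulationGrid(effect_sizes=[1.0], response_rates=[0.8],
                             subsample_fraction=1.0, n_replicate_runs=1)
    with pytest.raises(ValueError, match="replicates"):
        ns.run_power_grid(adata, grid, "pseudo_bulk")
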