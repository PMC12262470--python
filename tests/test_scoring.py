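"""Drug-score identities: target means, log transform, aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nephrosig as ns
from nephrosig.scoring import LOG_PSEUDOCOUNT
from conftest import make_adata


def _db(records):
    return ns.DrugTargetDB(
        [ns.DrugRecord(d, frozenset(t), bool(x)) for d, t, x in records]
    )


def test_target_matrix_rows_and_exclusions(caplog):
    db = _db([
        ("d1", {"A", "B"}, True),
        ("d2", {"Z"}, False),       # target absent from universe -> excluded
        ("d3", {"C"}, False),
    ])
    T, ids, tox = ns.build_target_matrix(db, ["A", "B", "C"])
    assert ids == ["d1", "d3"]
    assert T.toarray().tolist() == [[1, 1, 0], [0, 0, 1]]
    assert tox.tolist() == [True, False]


def test_target_matrix_count_oracle(small_db, detailed_lognorm):
    T, ids, _ = ns.build_target_matrix(small_db, list(detailed_lognorm.var_names))
    assert T.shape[0] == len(ids) <= len(small_db)


def test_score_is_mean_over_target_genes():
    X = np.array([[1.0, 3.0, 100.0], [2.0, 6.0, 7.0]])
    adata = make_adata(X, ["A", "B"])
    db = _db([("mono", {"G0"}, True), ("duo", {"G0", "G1"}, False)])
    T, ids, tox = ns.build_target_matrix(db, ["G0", "G1", "G2"])
    scores = ns.score_cells(adata, T, ids, tox)
    np.testing.assert_allclose(scores.raw[:, 0], X[:, 0])   # single target
    np.testing.assert_allclose(scores.raw[:, 1], [2.0, 4.0])  # mean of A,B
    # invariance to non-target gene values
    X2 = X.copy(); X2[:, 2] = 0.0
    scores2 = ns.score_cells(make_adata(X2, ["A", "B"]), T, ids, tox)
    np.testing.assert_allclose(scores.raw, scores2.raw)


def test_score_invariant_under_gene_permutation(detailed_lognorm, small_db):
    genes = list(detailed_lognorm.var_names)
    T, ids, tox = ns.build_target_matrix(small_db, genes)
    base = ns.score_cells(detailed_lognorm, T, ids, tox).raw
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(genes))
    shuffled = detailed_lognorm[:, perm].copy()
    T2, ids2, tox2 = ns.build_target_matrix(small_db, list(shuffled.var_names))
    permuted = ns.score_cells(shuffled, T2, ids2, tox2).raw
    np.testing.assert_allclose(base, permuted, atol=1e-12)


def test_score_monotone_in_target_expression():
    X = np.array([[1.0, 2.0]])
    db = _db([("d", {"G0", "G1"}, True)])
    T, ids, tox = ns.build_target_matrix(db, ["G0", "G1"])
    lo = ns.score_cells(make_adata(X, ["A"]), T, ids, tox).raw[0, 0]
    X_hi = X.copy(); X_hi[0, 0] += 1.0
    hi = ns.score_cells(make_adata(X_hi, ["A"]), T, ids, tox).raw[0, 0]
    assert hi > lo


def test_misaligned_universe_errors(detailed_lognorm, small_db):
    T, ids, tox = ns.build_target_matrix(small_db, list(detailed_lognorm.var_names))
    with pytest.raises(ValueError, match="genes"):
        ns.score_cells(detailed_lognorm[:, :10].copy(), T, ids, tox)


def test_log_transform_floor_and_monotonicity():
    raw = np.array([[0.0, 0.5, 2.0]])
    scores = ns.DrugScoreMatrix(
        raw=raw, drug_ids=["a", "b", "c"],
        nephrotoxic=np.array([True, False, False]),
        obs=pd.DataFrame({"detailed_type": ["T"], "abstract_type": ["T"],
                          "donor": ["D1"]}, index=["C0"]),
    )
    logged = ns.log_transform_scores(scores)
    assert logged.logged[0, 0] == pytest.approx(np.log(LOG_PSEUDOCOUNT))
    assert np.isfinite(logged.logged).all()
    assert logged.logged[0, 0] < logged.logged[0, 1] < logged.logged[0, 2]


def test_fold_change_convention_matches_printed_rows():
    """Natural-log convention: FC = e^logFC at the printed 3-decimal precision."""
    assert ns.fold_change_from_log(0.378) == pytest.approx(1.460, abs=2e-3)
    assert ns.fold_change_from_log(-0.524) == pytest.approx(0.592, abs=2e-3)


def test_aggregate_constant_type_and_cardinality(score_table, small_db, detailed_lognorm):
    # cardinality: one row per (drug, type) at each level
    T, ids, _ = ns.build_target_matrix(small_db, list(detailed_lognorm.var_names))
    n_types_det = detailed_lognorm.obs["detailed_type"].nunique()
    det = score_table[score_table["level"] == "detailed32"]
    ab = score_table[score_table["level"] == "abstract4"]
    assert len(det) == len(ids) * n_types_det
    assert len(ab) == len(ids) * 4
    # constant logged score -> aggregate equals it
    X = np.full((3, 2), 1.0)
    adata = make_adata(X, ["T"] * 3)
    db = _db([("d", {"G0"}, True)])
    Tm, ids2, tox2 = ns.build_target_matrix(db, ["G0", "G1"])
    logged = ns.log_transform_scores(ns.score_cells(adata, Tm, ids2, tox2))
    agg = ns.aggregate_by_cell_type(logged, "detailed32")
    assert agg["mean_log_score"].iloc[0] == pytest.approx(np.log(1.0 + LOG_PSEUDOCOUNT))


def test_aggregation_consistent_across_levels(detailed_lognorm, small_db):
    """Cell-count-weighted mean of detailed aggregates equals abstract aggregate."""
    T, ids, tox = ns.build_target_matrix(small_db, list(detailed_lognorm.var_names))
    logged = ns.log_transform_scores(ns.score_cells(detailed_lognorm, T, ids, tox))
    det = ns.aggregate_by_cell_type(logged, "detailed32")
    ab = ns.aggregate_by_cell_type(logged, "abstract4")
    counts = detailed_lognorm.obs.groupby(
        ["abstract_type", "detailed_type"], observed=True
    ).size()
    parent = detailed_lognorm.obs[["detailed_type", "abstract_type"]].drop_duplicates()
    det = det.merge(parent, left_on="cell_type", right_on="detailed_type")
    drug = ids[0]
    for parent_type in det["abstract_type"].unique():
        sub = det[(det["abstract_type"] == parent_type) & (det["drug_id"] == drug)]
        w = np.array([counts[(parent_type, t)] for t in sub["cell_type"]], dtype=float)
        weighted = np.average(sub["mean_log_score"], weights=w)
        expected = ab.loc[
            (ab["cell_type"] == parent_type) & (ab["drug_id"] == drug),
            "mean_log_score",
        ].iloc[0]
        assert weighted == pytest.approx(expected, abs=1e-9)
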