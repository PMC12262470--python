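"""Drug-nephrotoxicity classifiers on cell-type score features.

Each drug becomes one row whose features are its mean logged score in every
cell type (4 or 32 columns) and whose label is its nephrotoxicity flag.
Models are evaluated with stratified k-fold cross-validation; metrics are
computed on the pooled out-of-fold predictions, and the AUROC 95% CI by
stratified bootstrap of the pooled out-of-fold scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    VotingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

logger = logging.getLogger("nephrosig")

__all__ = ["EvalReport", "MODEL_FAMILIES", "build_feature_table", "cross_validate"]

#: Canonical model-family names, in reporting order.
MODEL_FAMILIES = (
    "logistic_regression",
    "svm",
    "random_forest",
    "extra_trees",
    "gradient_boosting",
    "xgboost",
    "ensemble",
    "mlp",
)


@dataclass(frozen=True)
class EvalReport:
    model_name: str
    accuracy: float
    f1: float
    auroc: float
    sensitivity: float
    specificity: float
    auroc_ci_lower: float
    auroc_ci_upper: float
    auroc_ci_method: str = "stratified bootstrap, 2000 resamples"

    def __post_init__(self) -> None:
        for m in (self.accuracy, self.f1, self.auroc, self.sensitivity, self.specificity):
            if not 0.0 <= m <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def build_feature_table(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Pivot the long cell-type score table to drugs x cell types.

    Column order is sorted type names; the label column ``nephrotoxic``
    comes last.  Errors if any drug lacks a cell-type column.
    """
    sub = table[table["level"] == level]
    if sub.empty:
        raise ValueError(f"no rows at level {level!r}")
    wide = sub.pivot(index="drug_id", columns="cell_type", values="mean_log_score")
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"drugs missing scores in cell types {missing}")
    labels = sub.drop_duplicates("drug_id").set_index("drug_id")["nephrotoxic"]
    wide["nephrotoxic"] = labels.reindex(wide.index).astype(bool)
    return wide


def _make_model(family: str, seed: int):
    if family == "logistic_regression":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if family == "svm":
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed)
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "xgboost":
        return XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0
        )
    if family == "ensemble":
        members = [
            (f, _make_model(f, seed))
            for f in MODEL_FAMILIES[:6]  # soft vote over the six base learners
        ]
        return VotingClassifier(members, voting="soft", n_jobs=1)
    if family == "mlp":
        return make_pipeline(
            StandardScaler(), MLPClassifier(max_iter=800, random_state=seed)
        )
    raise ValueError(f"unknown model family {family!r}")


def _bootstrap_auroc_ci(
    y: np.ndarray, scores: np.ndarray, seed: int, n_boot: int = 2000
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        vals[b] = roc_auc_score(y[idx], scores[idx])
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return float(lo), float(hi)


def cross_validate(
    features: pd.DataFrame, model_family: str, k: int = 5, seed: int = 0
) -> EvalReport:
    """Stratified k-fold evaluation of one model family.

    Metrics are computed on pooled out-of-fold predictions; the positive
    class is nephrotoxic, so sensitivity is recall on nephrotoxic drugs.
    Fully deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = features["nephrotoxic"].to_numpy(dtype=bool)
    X = features.drop(columns="nephrotoxic").to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    oof_score = np.full(len(y), np.nan)
    oof_label = np.zeros(len(y), dtype=bool)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:
        raise ValueError("could not build folds with both classes after 10 attempts")

    for tr, te in folds:
        model = _make_model(model_family, seed)
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])[:, list(model.classes_).index(True)]
        oof_score[te] = proba
        oof_label[te] = model.predict(X[te]).astype(bool)

    tp = np.sum(oof_label & y)
    tn = np.sum(~oof_label & ~y)
    sens = tp / y.sum()
    spec = tn / (~y).sum()
    auroc = roc_auc_score(y, oof_score)
    lo, hi = _bootstrap_auroc_ci(y, oof_score, seed)
    report = EvalReport(
        model_name=model_family,
        accuracy=float(accuracy_score(y, oof_label)),
        f1=float(f1_score(y, oof_label)),
        auroc=float(auroc),
        sensitivity=float(sens),
        specificity=float(spec),
        auroc_ci_lower=float(min(lo, auroc)),
        auroc_ci_upper=float(max(hi, auroc)),
    )
    logger.info(
        "classify: %s acc=%.3f f1=%.3f auroc=%.3f", model_family,
        report.accuracy, report.f1, report.auroc,
    )
    return report


def evaluate_families(
    features: pd.DataFrame,
    families=MODEL_FAMILIES,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate several model families; one report row per family."""
    reports = [cross_validate(features, f, k=k, seed=seed) for f in families]
    return pd.DataFrame([r.__dict__ for r in reports])
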