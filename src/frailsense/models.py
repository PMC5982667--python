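"""One-vs-rest discrimination models for pre-frailty and their evaluation.

Four decision-tree models discriminate pre-frail subjects from the pooled
non-frail and frail groups:

    step      total steps (N/1000), longest unbroken stepping bout
    pap       total walk %, longest unbroken walking bout
    pab       total sedentary (h), total MtV (min)
    combined  the union of the above

Each model is evaluated by stratified 5-fold cross validation; sensitivity,
specificity, and accuracy (in %) come from the tree's label output on the
held-out fold, the AUC from its class scores via the Mann-Whitney statistic
with half credit for ties.  Reported values are the mean +- SD over folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .frailty_clinical import STATUS_PRE_FRAIL

MODEL_FEATURES: dict[str, list[str]] = {
    "step": ["total_steps_k", "longest_step_bout_n"],
    "pap": ["walk_pct", "longest_walk_s"],
    "pab": ["total_sed_h", "total_mtv_min"],
}
MODEL_FEATURES["combined"] = (MODEL_FEATURES["step"] + MODEL_FEATURES["pap"]
                              + MODEL_FEATURES["pab"])

DEFAULT_FOLDS = 5
DEFAULT_MAX_DEPTH = 3
DEFAULT_MIN_LEAF = 5


@dataclass
class ModelSpec:
    name: str
    features: list[str]
    folds: int = DEFAULT_FOLDS
    max_depth: int = DEFAULT_MAX_DEPTH
    min_samples_leaf: int = DEFAULT_MIN_LEAF
    seed: int = 0

    @classmethod
    def named(cls, name: str, **kwargs) -> "ModelSpec":
        if name not in MODEL_FEATURES:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_FEATURES)}")
        return cls(name=name, features=list(MODEL_FEATURES[name]), **kwargs)


@dataclass
class ModelReport:
    """Cross-validated performance: per-fold metrics and their mean +- SD."""

    model: str
    sensitivity: tuple[float, float] = (np.nan, np.nan)
    specificity: tuple[float, float] = (np.nan, np.nan)
    accuracy: tuple[float, float] = (np.nan, np.nan)
    auc: tuple[float, float] = (np.nan, np.nan)
    fold_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {"model": self.model,
                "sensitivity_pct": {"mean": self.sensitivity[0], "sd": self.sensitivity[1]},
                "specificity_pct": {"mean": self.specificity[0], "sd": self.specificity[1]},
                "accuracy_pct": {"mean": self.accuracy[0], "sd": self.accuracy[1]},
                "auc": {"mean": self.auc[0], "sd": self.auc[1]}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def roc_auc(scores, labels) -> float:
    """Area under the one-vs-rest ROC curve.

    Computed as the Mann-Whitney probability that a random positive outscores
    a random negative, with half credit for ties; requires at least one
    positive and one negative.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return {
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
        "accuracy_pct": 100.0 * (tp + tn) / y_true.shape[0],
        "auc": roc_auc(scores, y_true),
    }


def crossvalidate(spec: ModelSpec, cohort: pd.DataFrame) -> ModelReport:
    """Stratified k-fold cross validation of one model on a cohort table.

    The positive class is pre-frail; all other statuses are pooled.  Each
    class must populate every fold, which stratification guarantees whenever
    both classes have at least ``folds`` members.
    """
    missing = [f for f in spec.features if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks features: {missing}")
    X = cohort[spec.features].to_numpy(dtype=np.float64)
    y = (cohort["status"] == STATUS_PRE_FRAIL).astype(int).to_numpy()
    if min(np.sum(y == 1), np.sum(y == 0)) < spec.folds:
        raise ValueError("too few members of a class for stratified folds")

    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = []
    for train, test in cv.split(X, y):
        clf = DecisionTreeClassifier(max_depth=spec.max_depth,
                                     min_samples_leaf=spec.min_samples_leaf,
                                     random_state=spec.seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        scores = clf.predict_proba(X[test])[:, 1]
        folds.append(_fold_metrics(y[test], pred, scores))
    frame = pd.DataFrame(folds)

    def agg(col: str) -> tuple[float, float]:
        return float(frame[col].mean()), float(frame[col].std(ddof=1))

    return ModelReport(model=spec.name,
                       sensitivity=agg("sensitivity_pct"),
                       specificity=agg("specificity_pct"),
                       accuracy=agg("accuracy_pct"),
                       auc=agg("auc"),
                       fold_metrics=frame)


def evaluate_all(cohort: pd.DataFrame, seed: int = 0,
                 folds: int = DEFAULT_FOLDS) -> dict[str, ModelReport]:
    """Cross-validate the four named models on one cohort."""
    return {name: crossvalidate(ModelSpec.named(name, seed=seed, folds=folds), cohort)
            for name in MODEL_FEATURES}
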