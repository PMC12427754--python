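"""Seven-classifier zoo with leak-proof tuning and Youden-J calibration.

Families: shallow neural net (NN), deeper neural net (DNN), gradient-boosted
trees (XGB), RBF support-vector machine (SVM), random forest (RF), logistic
regression (LR), decision tree (DT). Every family is wrapped in the fixed
pipeline resample (SMOTE) -> scale (z-score) -> classify, so oversampled
points and scaler statistics are derived only from the training side of each
cross-validation fold.

Hyperparameters are tuned by randomized search with stratified 5-fold CV
scored by ROC AUC; the winner is refit on the full training set. The
decision threshold is calibrated by maximizing Youden's J
(sensitivity + specificity - 1), by default on pooled out-of-fold training
scores, then fixed for test-set evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from tepmced.nnet import MLPBinaryClassifier
from tepmced.resample import ResampleScalePipeline

logger = logging.getLogger(__name__)

FAMILIES = ("NN", "DNN", "XGB", "SVM", "RF", "LR", "DT")

# Tuned grids. All families use fixed, conventional spaces kept in this
# versioned module so results are reproducible.
_NET_SPACE = {
    "hidden_units": [64, 128],
    "dropout": [0.1, 0.3],
    "learning_rate": [0.001, 0.0005],
    "epochs": [20, 30],
    "batch_size": [32, 64],
}

SEARCH_SPACES: dict[str, dict[str, list]] = {
    "NN": _NET_SPACE,
    "DNN": _NET_SPACE,
    "XGB": {
        "n_estimators": [100, 200, 300],
        "max_depth": [3, 4, 6],
        "learning_rate": [0.05, 0.1, 0.3],
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.8, 1.0],
    },
    "SVM": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": ["scale", 0.01, 0.001],
    },
    "RF": {
        "n_estimators": [100, 200, 300],
        "max_depth": [6, 10, 16],
        "max_features": ["sqrt", 0.3],
        "min_samples_leaf": [1, 3, 5],
    },
    "LR": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0],
    },
    "DT": {
        "max_depth": [3, 5, 8, 12],
        "min_samples_leaf": [1, 5, 10],
        "criterion": ["gini", "entropy"],
    },
}

DEFAULT_SEARCH_ITERS = {"NN": 8, "DNN": 5, "XGB": 10, "SVM": 8, "RF": 10, "LR": 5, "DT": 8}


@dataclass
class ModelConfig:
    family: str
    search_space: dict[str, list] | None = None
    n_search_iters: int | None = None
    cv_folds: int = 5
    seed: int = 42
    use_smote: bool = True
    threshold_source: str = "oof"  # {"oof", "refit"}

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.search_space is None:
            self.search_space = SEARCH_SPACES[self.family]
        if self.n_search_iters is None:
            self.n_search_iters = DEFAULT_SEARCH_ITERS[self.family]
        if self.threshold_source not in ("oof", "refit"):
            raise ValueError("threshold_source must be 'oof' or 'refit'")


@dataclass
class TrainedModel:
    family: str
    best_params: dict
    pipeline: ResampleScalePipeline
    threshold: float
    cv_auc: float
    fold_aucs: list[float] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def predict_scores(self, X) -> np.ndarray:
        return self.pipeline.decision_scores(np.asarray(X, dtype=float))

    def predict_labels(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold).astype(int)


def _make_classifier(family: str, params: dict, seed: int):
    if family == "NN":
        return MLPBinaryClassifier(n_hidden_layers=1, seed=seed, **params)
    if family == "DNN":
        return MLPBinaryClassifier(n_hidden_layers=2, seed=seed, **params)
    if family == "XGB":
        return XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0, **params
        )
    if family == "SVM":
        # probability outputs via the standard Platt-scaling calibration
        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **params), method="sigmoid", ensemble=False
        )
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def build_model(config: ModelConfig, params: dict | None = None) -> ResampleScalePipeline:
    """Untrained resample -> scale -> classify pipeline for the family.

    ``params`` defaults to the first point of the family's search space.
    """
    if params is None:
        params = {k: v[0] for k, v in config.search_space.items()}
    clf = _make_classifier(config.family, params, config.seed)
    return ResampleScalePipeline(clf, seed=config.seed, use_smote=config.use_smote)


def calibrate_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J over midpoints of sorted unique scores.

    Ties resolve to the smallest qualifying threshold; the candidate set also
    includes one point below the minimum and above the maximum score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes are required to calibrate a threshold")
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1e-6], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-6]])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(np.clip(best_t, 0.0, 1.0))


def _cv_auc(config: ModelConfig, params: dict, X: np.ndarray, y: np.ndarray,
            collect_oof: bool = False) -> tuple[float, list[float], np.ndarray | None]:
    """Stratified k-fold AUC of one hyperparameter point; oversampling and
    scaling are fitted inside each fold's training part only."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    fold_aucs: list[float] = []
    oof = np.full(y.size, np.nan) if collect_oof else None
    for tr_idx, va_idx in skf.split(X, y):
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[va_idx])) < 2:
            warnings.warn("skipping single-class fold", stacklevel=2)
            continue
        pipe = build_model(config, params)
        pipe.fit(X[tr_idx], y[tr_idx])
        s = pipe.decision_scores(X[va_idx])
        fold_aucs.append(float(roc_auc_score(y[va_idx], s)))
        if collect_oof:
            oof[va_idx] = s
    if not fold_aucs:
        raise RuntimeError("all cross-validation folds were skipped")
    return float(np.mean(fold_aucs)), fold_aucs, oof


def tune_and_fit(X, y, config: ModelConfig, genes: list[str] | None = None) -> TrainedModel:
    """Randomized search + stratified CV + refit + threshold calibration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    sampler = list(
        ParameterSampler(config.search_space, n_iter=config.n_search_iters, random_state=config.seed)
    )
    best_auc, best_params, best_folds = -np.inf, None, []
    for params in sampler:
        mean_auc, fold_aucs, _ = _cv_auc(config, params, X, y)
        if mean_auc > best_auc:
            best_auc, best_params, best_folds = mean_auc, params, fold_aucs

    # refit the winner on the full training set
    pipeline = build_model(config, best_params)
    pipeline.fit(X, y)

    if config.threshold_source == "oof":
        _, _, oof = _cv_auc(config, best_params, X, y, collect_oof=True)
        mask = ~np.isnan(oof)
        threshold = calibrate_threshold(oof[mask], y[mask])
    else:
        threshold = calibrate_threshold(pipeline.decision_scores(X), y)

    return TrainedModel(
        family=config.family,
        best_params=dict(best_params),
        pipeline=pipeline,
        threshold=threshold,
        cv_auc=best_auc,
        fold_aucs=list(best_folds),
        genes=list(genes) if genes is not None else [],
    )
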