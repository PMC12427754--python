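"""Evaluation metrics and stage-/type-stratified detection breakdowns."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )


@dataclass
class MetricsReport:
    """Point metrics from a confusion matrix plus rank metrics from scores.

    Metrics whose denominator is empty are reported as ``nan`` with the
    affected name listed in ``undefined`` (never silently 0).
    """

    auc: float = float("nan")
    ap: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    precision: float = float("nan")
    f1: float = float("nan")
    accuracy: float = float("nan")
    balanced_accuracy: float = float("nan")
    undefined: list[str] = field(default_factory=list)
    per_stage: pd.DataFrame | None = None
    per_type: pd.DataFrame | None = None

    def to_dict(self, ndigits: int = 3) -> dict:
        out = {}
        for k in ("auc", "ap", "sensitivity", "specificity", "precision", "f1",
                  "accuracy", "balanced_accuracy"):
            v = getattr(self, k)
            out[k] = None if np.isnan(v) else round(float(v), ndigits)
        out["undefined"] = list(self.undefined)
        return out


def classification_metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> MetricsReport:
    """Standard binary-screening metrics.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/n,
    F1 = 2TP/(2TP+FP+FN), balanced accuracy = (sens+spec)/2.
    AUC and average precision are computed from ``scores`` when given.
    """
    rep = MetricsReport()

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            rep.undefined.append(name)
            return float("nan")
        return num / den

    rep.sensitivity = safe(cm.tp, cm.tp + cm.fn, "sensitivity")
    rep.specificity = safe(cm.tn, cm.tn + cm.fp, "specificity")
    rep.precision = safe(cm.tp, cm.tp + cm.fp, "precision")
    rep.accuracy = safe(cm.tp + cm.tn, cm.n, "accuracy")
    rep.f1 = safe(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    rep.balanced_accuracy = (rep.sensitivity + rep.specificity) / 2.0

    if scores is not None and labels is not None:
        labels = np.asarray(labels).astype(int)
        if labels.min() != labels.max():
            rep.auc = float(roc_auc_score(labels, scores))
            rep.ap = float(average_precision_score(labels, scores))
        else:
            rep.undefined.extend(["auc", "ap"])
    return rep


def stratified_accuracy(
    predictions: np.ndarray,
    metadata: pd.DataFrame,
    stratum: str,
) -> pd.DataFrame:
    """Per-stratum recall among cancer samples; controls form their own
    stratum scored as the correct-rejection (specificity) rate.

    ``stratum`` is ``"stage"`` or ``"cancer_type"``; empty strata are
    flagged undefined.
    """
    if stratum not in metadata.columns:
        raise KeyError(f"metadata lacks column {stratum!r}")
    pred = np.asarray(predictions).astype(int)
    meta = metadata.reset_index(drop=True)
    is_cancer = (meta["label"] == "cancer").to_numpy()

    rows = []
    strata = sorted(meta.loc[is_cancer, stratum].astype(str).unique())
    for s in strata:
        mask = is_cancer & (meta[stratum].astype(str) == s).to_numpy()
        n = int(mask.sum())
        rows.append(
            {
                "stratum": s,
                "n": n,
                "accuracy": float(pred[mask].mean()) if n else float("nan"),
                "undefined": n == 0,
            }
        )
    n_ctrl = int((~is_cancer).sum())
    rows.append(
        {
            "stratum": "control",
            "n": n_ctrl,
            "accuracy": float((pred[~is_cancer] == 0).mean()) if n_ctrl else float("nan"),
            "undefined": n_ctrl == 0,
        }
    )
    return pd.DataFrame(rows)


def cross_model_average(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-model stratum accuracies (models as columns)."""
    merged = None
    for model, t in tables.items():
        cur = t.set_index("stratum")["accuracy"].rename(model)
        merged = cur.to_frame() if merged is None else merged.join(cur, how="outer")
    out = merged.mean(axis=1, skipna=True).rename("mean_accuracy").reset_index()
    return out
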