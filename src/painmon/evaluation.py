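"""Evaluation: micro-averaged F1 over pain classes, MSE, and ICC(3,1).

The micro F1 pools true/false positives and false negatives over the pain
classes only — the no-pain class is excluded from pooling, so the trivial
all-no-pain predictor scores exactly 0 (a no-pain prediction on a pain
window is a pooled false negative; a pain prediction on a no-pain window a
pooled false positive).

ICC(3,1) is the two-way mixed-effects, consistency, single-rater
intraclass correlation with k = 2 raters (prediction and ground truth),
computed from the two-way ANOVA decomposition:

    ICC = (MS_rows - MS_resid) / (MS_rows + (k - 1) * MS_resid)

with windows as rows and raters as columns.  A constant prediction paired
with a non-constant truth yields exactly 0; two constant vectors leave the
coefficient undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .datasets import class_to_continuous


def micro_f1(y_true: np.ndarray, y_pred: np.ndarray, bl_class: int = 0) -> float:
    """Micro-averaged F1 in percent, pooled over pain classes only."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    pain_true = y_true != bl_class
    pain_pred = y_pred != bl_class
    tp = int(np.sum(pain_true & (y_pred == y_true)))
    fp = int(np.sum(pain_pred & (y_pred != y_true)))
    fn = int(np.sum(pain_true & (y_pred != y_true)))
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 100.0 * 2 * tp / denom


def mse(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean squared error on the normalized [0, 1] intensity scale."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise ValueError("length mismatch between truth and predictions")
    return float(np.mean((y_pred - y_true) ** 2))


def icc_3_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(3,1) between two paired measurement vectors (k = 2 raters)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two 1-D vectors of equal length")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return float("nan")
    k = 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_resid = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_resid = ss_resid / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_resid
    if denom == 0:
        return float("nan")
    return float((ms_rows - ms_resid) / denom)


@dataclass
class EvaluationReport:
    """Metric table with one row per (dataset, model, modality) cell."""

    rows: list[dict[str, Any]] = field(default_factory=list)

    def add(self, dataset_id: str, model_id: str, modality: str, *,
            micro_f1_percent: float | None = None, mse: float | None = None,
            icc: float | None = None, **metadata: Any) -> None:
        self.rows.append({
            "dataset": dataset_id, "model": model_id, "modality": modality,
            "micro_f1_percent": micro_f1_percent, "mse": mse, "icc": icc,
            **metadata,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, csv_path, json_path=None) -> None:
        df = self.to_frame()
        df.to_csv(csv_path, index=False)
        if json_path is not None:
            df.to_json(json_path, orient="records", indent=2)


def evaluate_classification(y_class: np.ndarray, pred_class: np.ndarray,
                            n_classes: int) -> dict[str, float]:
    """All three metrics for a classifier, scoring MSE/ICC on the
    class-to-intensity mapping (quality ignored for 7-class datasets)."""
    cont_true = class_to_continuous(y_class, n_classes)
    cont_pred = class_to_continuous(pred_class, n_classes)
    return {
        "micro_f1_percent": micro_f1(y_class, pred_class),
        "mse": mse(cont_pred, cont_true),
        "icc": icc_3_1(cont_pred, cont_true),
    }


def evaluate_regression(y_cont: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    return {
        "micro_f1_percent": None,
        "mse": mse(pred, y_cont),
        "icc": icc_3_1(np.asarray(pred, dtype=float), np.asarray(y_cont, dtype=float)),
    }
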