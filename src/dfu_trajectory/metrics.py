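"""Evaluation suite for three-category transition prediction.

Reports balanced accuracy (mean of per-class recalls — the headline
"accuracy" for this task), per-class precision/recall/F1 and weighted F1,
one-vs-rest TPR/FPR/TNR/FNR, per-class and mean one-vs-rest ROC-AUC,
per-class and mean expected calibration error, and the 3x3 confusion
matrix, aggregated per fold as mean ± sd.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, precision_recall_fscore_support, roc_auc_score

from .transition_labels import CATEGORIES


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls over classes present in the truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float((y_pred[mask] == c).mean()))
    missing = set(CATEGORIES) - set(np.unique(y_true))
    if missing:
        warnings.warn(f"class(es) absent from truth, excluded: {sorted(missing)}")
    return float(np.mean(recalls))


def ovr_rates(y_true, y_pred, positive_class) -> dict[str, float]:
    """One-vs-rest TPR/FPR/TNR/FNR for one class.

    TPR = TP / actual positives, FPR = FP / actual negatives; the
    complementarity identities TPR+FNR=1 and TNR+FPR=1 hold exactly. A rate
    with an empty denominator is reported as NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_class
    pred_pos = y_pred == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    tpr = float((pred_pos & pos).sum() / n_pos) if n_pos else np.nan
    fpr = float((pred_pos & ~pos).sum() / n_neg) if n_neg else np.nan
    return {
        "TPR": tpr,
        "FPR": fpr,
        "TNR": 1.0 - fpr if n_neg else np.nan,
        "FNR": 1.0 - tpr if n_pos else np.nan,
    }


def mean_ovr_auc(y_true, proba: np.ndarray, classes=CATEGORIES):
    """Per-class one-vs-rest rank AUCs and their unweighted mean.

    Classes with single-valued truth (no positives or no negatives) are
    undefined and reported NaN; the mean spans the defined classes.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    per_class = {}
    for j, c in enumerate(classes):
        pos = (y_true == c).astype(int)
        if pos.min() == pos.max():
            per_class[c] = np.nan
            continue
        per_class[c] = float(roc_auc_score(pos, proba[:, j]))
    vals = [v for v in per_class.values() if not np.isnan(v)]
    mean = float(np.mean(vals)) if vals else np.nan
    return per_class, mean


def ece(y_true_binary, proba, n_bins: int = 10) -> float:
    """Expected calibration error over equal-width probability bins.

    ECE = sum_b (n_b / N) * |acc_b - conf_b|, where conf_b is the mean
    predicted probability in bin b and acc_b the observed positive
    frequency.
    """
    y = np.asarray(y_true_binary, dtype=float)
    p = np.asarray(proba, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    total = 0.0
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        total += mask.mean() * abs(y[mask].mean() - p[mask].mean())
    return float(total)


def reliability_points(y_true_binary, proba, n_bins: int = 10) -> pd.DataFrame:
    """Per-bin (confidence, observed frequency, count) for calibration curves."""
    y = np.asarray(y_true_binary, dtype=float)
    p = np.asarray(proba, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": int(mask.sum()),
                "mean_confidence": float(p[mask].mean()) if mask.any() else np.nan,
                "observed_frequency": float(y[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def confusion(y_true, y_pred, classes=CATEGORIES) -> pd.DataFrame:
    m = _sk_confusion(y_true, y_pred, labels=list(classes))
    return pd.DataFrame(m, index=list(classes), columns=list(classes))


@dataclass
class EvaluationReport:
    """Full per-fold and aggregate evaluation of a cross-validated run."""

    per_fold: pd.DataFrame                  # fold, balanced_accuracy, weighted_f1, n
    per_class: pd.DataFrame                 # class, precision, recall, f1, rates, auc, ece
    confusion_matrix: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary,
                "per_fold": self.per_fold.to_dict(orient="records"),
                "per_class": self.per_class.to_dict(orient="records"),
                "confusion_matrix": self.confusion_matrix.to_dict(),
            },
            indent=2,
            default=float,
        )

    def render_text(self) -> str:
        lines = ["Cross-validated transition prediction", "=" * 40]
        lines.append(self.per_fold.to_string(index=False))
        lines.append("")
        lines.append(self.per_class.to_string(index=False))
        lines.append("")
        lines.append("Confusion matrix (rows = truth):")
        lines.append(self.confusion_matrix.to_string())
        return "\n".join(lines)


def evaluate_run(
    predictions: pd.DataFrame,
    n_bins: int = 10,
) -> EvaluationReport:
    """Evaluate a prediction table with columns ``fold``, ``y_true``,
    ``y_pred`` and per-class probability columns ``proba_<class>``.

    Per-fold balanced accuracy and weighted F1 are aggregated mean ± sd;
    per-class metrics are computed on the pooled out-of-fold predictions.
    """
    req = {"fold", "y_true", "y_pred"} | {f"proba_{c}" for c in CATEGORIES}
    missing = req - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing column(s): {sorted(missing)}")

    fold_rows = []
    for fold, grp in predictions.groupby("fold"):
        fold_rows.append(
            {
                "fold": fold,
                "balanced_accuracy": balanced_accuracy(grp["y_true"], grp["y_pred"]),
                "weighted_f1": float(
                    f1_score(grp["y_true"], grp["y_pred"], average="weighted", zero_division=0)
                ),
                "n": len(grp),
            }
        )
    per_fold = pd.DataFrame(fold_rows)

    y_true = predictions["y_true"].to_numpy()
    y_pred = predictions["y_pred"].to_numpy()
    proba = predictions[[f"proba_{c}" for c in CATEGORIES]].to_numpy(dtype=float)

    prec, rec, f1c, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CATEGORIES), zero_division=0
    )
    aucs, auc_mean = mean_ovr_auc(y_true, proba)
    class_rows = []
    for j, c in enumerate(CATEGORIES):
        rates = ovr_rates(y_true, y_pred, c)
        pos = (y_true == c).astype(float)
        class_rows.append(
            {
                "class": c,
                "precision": float(prec[j]),
                "recall": float(rec[j]),
                "f1": float(f1c[j]),
                **rates,
                "auc": aucs[c],
                "ece": ece(pos, proba[:, j], n_bins=n_bins),
            }
        )
    per_class = pd.DataFrame(class_rows)

    summary = {
        "balanced_accuracy_mean": float(per_fold["balanced_accuracy"].mean()),
        "balanced_accuracy_sd": float(per_fold["balanced_accuracy"].std(ddof=0)),
        "weighted_f1_mean": float(per_fold["weighted_f1"].mean()),
        "weighted_f1_sd": float(per_fold["weighted_f1"].std(ddof=0)),
        "mean_ovr_auc": auc_mean,
        "mean_ece": float(np.nanmean(per_class["ece"].to_numpy())),
        "n_samples": int(len(predictions)),
    }
    return EvaluationReport(
        per_fold=per_fold,
        per_class=per_class,
        confusion_matrix=confusion(y_true, y_pred),
        summary=summary,
    )
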