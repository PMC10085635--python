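"""Confusion-based metrics, ROC/PR curves and per-TF summaries.

AUROC is the trapezoidal area under the (FPR, TPR) curve; AUPRC uses the
step-wise (non-interpolated) precision estimator, which avoids the optimism
of linear PR interpolation.  Tied scores enter and leave the confusion table
together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .labels import PairSample


@dataclass
class EvalResult:
    scores: np.ndarray
    labels: np.ndarray
    roc: np.ndarray  # (n_points, 2): FPR, TPR
    pr: np.ndarray  # (n_points, 2): Recall, Precision
    auroc: float
    auprc: float
    per_tf: dict[str, dict] = field(default_factory=dict)


def confusion_counts(labels, predictions) -> dict[str, float]:
    """TP/FP/TN/FN at fixed binary predictions, plus the derived rates."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    def _safe(num, den):
        return num / den if den else float("nan")
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "TPR": _safe(tp, tp + fn),
        "FPR": _safe(fp, fp + tn),
        "Recall": _safe(tp, tp + fn),
        "Precision": _safe(tp, tp + fp),
    }


def roc_pr_curves(labels, scores) -> EvalResult:
    """Threshold sweep over the unique scores; AUROC and step-wise AUPRC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute ROC/PR")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return EvalResult(
        scores=scores,
        labels=labels,
        roc=np.column_stack([fpr, tpr]),
        pr=np.column_stack([recall[::-1], precision[::-1]]),
        auroc=float(auc(fpr, tpr)),
        auprc=float(average_precision_score(labels, scores)),
    )


def per_tf_summary(
    labels, scores, samples: list[PairSample]
) -> dict[str, dict]:
    """Per-TF-group AUROC/AUPRC and class counts; single-class groups flagged."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    out: dict[str, dict] = {}
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(s.tf_group, []).append(i)
    for tf, idx in sorted(groups.items()):
        yl, ys = labels[idx], scores[idx]
        n_pos, n_neg = int((yl == 1).sum()), int((yl == 0).sum())
        if n_pos and n_neg:
            r = roc_pr_curves(yl, ys)
            out[tf] = {"auroc": r.auroc, "auprc": r.auprc,
                       "n_pos": n_pos, "n_neg": n_neg}
        else:
            out[tf] = {"auroc": float("nan"), "auprc": float("nan"),
                       "n_pos": n_pos, "n_neg": n_neg}
    return out


def evaluate(
    scores, labels, samples: list[PairSample] | None = None
) -> EvalResult:
    """Full evaluation; attaches per-TF summaries when samples are given."""
    result = roc_pr_curves(labels, scores)
    if samples is not None:
        result.per_tf = per_tf_summary(labels, scores, samples)
    return result


def save_report(result: EvalResult, directory) -> None:
    """Metrics + curve points as TSV for external plotting."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"metric": ["auroc", "auprc", "n_pos", "n_neg"],
         "value": [result.auroc, result.auprc,
                   int((result.labels == 1).sum()), int((result.labels == 0).sum())]}
    ).to_csv(d / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame(result.roc, columns=["fpr", "tpr"]).to_csv(
        d / "roc_curve.tsv", sep="\t", index=False
    )
    pd.DataFrame(result.pr, columns=["recall", "precision"]).to_csv(
        d / "pr_curve.tsv", sep="\t", index=False
    )
    if result.per_tf:
        pd.DataFrame(
            [{"tf": tf, **v} for tf, v in result.per_tf.items()]
        ).to_csv(d / "per_tf.tsv", sep="\t", index=False)
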