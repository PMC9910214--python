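"""Binary-classification metrics and slice-weight visualization.

Metrics: accuracy, precision, recall and F1 from the confusion counts
(acc = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2*precision*recall/(precision+recall)), plus threshold-free ROC-AUC
and average precision. Scores are positive-class probabilities; the
decision threshold is 0.5 with ties predicted positive. A ratio with a
zero denominator is reported as 0 and flagged (degenerate folds only).

The visualization mirrors the model-introspection figure of the method:
per-slice raw logits, their softmax weights (a curve summing to 1 whose
peaks mark the slices the model found informative), and the fused image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "basic_metrics",
    "roc_auc",
    "average_precision",
    "evaluate",
    "visualize_slices",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    acc: float
    auc: float
    f1: float
    precision: float
    recall: float
    ap: float
    confusion: ConfusionCounts
    threshold: float = 0.5
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "auc": self.auc, "f1": self.f1,
            "precision": self.precision, "recall": self.recall, "ap": self.ap,
            "threshold": self.threshold,
            "confusion": {"TP": self.confusion.TP, "TN": self.confusion.TN,
                          "FP": self.confusion.FP, "FN": self.confusion.FN},
            "warnings": list(self.warnings),
        }


def _check_pair(labels, scores):
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels, scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a threshold; score == threshold predicts positive."""
    labels, scores = _check_pair(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def basic_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, list[str]]:
    """(acc, precision, recall, f1) plus warning flags for 0/0 ratios."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    warnings: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.append(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    acc = (c.TP + c.TN) / c.total
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    recall = ratio(c.TP, c.TP + c.FN, "recall")
    if precision + recall == 0:
        warnings.append("f1 undefined (precision + recall = 0); reported as 0")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return acc, precision, recall, f1, warnings


def roc_auc(labels, scores) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 0.5."""
    labels, scores = _check_pair(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(labels, scores))


def average_precision(labels, scores) -> float:
    """Step-interpolated AP: sum over thresholds of (R_n - R_{n-1}) * P_n."""
    labels, scores = _check_pair(labels, scores)
    if (labels == 1).sum() == 0:
        raise ValueError("average_precision requires at least one positive")
    return float(average_precision_score(labels, scores))


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report from labels and positive-class scores."""
    labels, scores = _check_pair(labels, scores)
    c = confusion(labels, scores, threshold)
    acc, precision, recall, f1, warnings = basic_metrics(c)
    both_classes = len(np.unique(labels)) == 2
    if both_classes:
        auc = roc_auc(labels, scores)
    else:
        auc = 0.0
        warnings.append("auc undefined (single-class labels); reported as 0")
    if (labels == 1).any():
        ap = average_precision(labels, scores)
    else:
        ap = 0.0
        warnings.append("ap undefined (no positives); reported as 0")
    return EvalReport(acc=acc, auc=auc, f1=f1, precision=precision,
                      recall=recall, ap=ap, confusion=c, threshold=threshold,
                      warnings=warnings)


def visualize_slices(model, v, out_dir: str | Path) -> list[Path]:
    """Emit the three per-volume diagnostics: logit curve, weight curve,
    fused image (PNG), plus a CSV of logits/weights.

    Requires an LWP-pooling model. Returns the created figure paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .fusion import fuse_lwp
    from .network import prepare_stack, slice_weights

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sw = slice_weights(model, v)
    stack = prepare_stack(v, model.config)
    fused = fuse_lwp(stack, sw.weights)
    t = np.arange(len(sw.logits))

    paths = []
    for name, values, ylabel in (("logits", sw.logits, "slice logit Q_t"),
                                 ("weights", sw.weights, "softmax weight alpha_t")):
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(t, values, marker="o", ms=3)
        ax.set_xlabel("slice index t")
        ax.set_ylabel(ylabel)
        ax.set_title(f"{v.id}: per-slice {name}")
        fig.tight_layout()
        p = out_dir / f"{v.id}_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(fused.pixels, cmap="gray")
    ax.set_title(f"{v.id}: fused image ({model.config.view})")
    ax.axis("off")
    fig.tight_layout()
    p = out_dir / f"{v.id}_fused.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    csv_path = out_dir / f"{v.id}_slice_weights.csv"
    np.savetxt(csv_path, np.column_stack([t, sw.logits, sw.weights]),
               delimiter=",", header="slice,logit,weight", comments="")
    return paths
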