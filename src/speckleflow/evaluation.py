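"""Classification metrics: confusion matrices, per-class P/R/F1, label merging.

Metrics are computed at chunk level (each 64-frame window is one test
sample); video-level majority votes can be reported separately.  The
merged-label variant collapses the zero- and low-flow classes — clinically
both are "compromised flow" — into one class, a coarsening that can only
increase accuracy on fixed predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import FlowCondition

__all__ = [
    "ClassificationReport",
    "confusion_matrix",
    "report",
    "merge_zero_low",
    "MERGED_CLASS_NAMES",
    "run_report",
]

#: label mapping of the merged scheme: ZERO and LOW collapse to class 0.
ZERO_LOW_MERGE_MAP: dict[int, int] = {
    int(FlowCondition.ZERO): 0,
    int(FlowCondition.LOW): 0,
    int(FlowCondition.MEDIUM): 1,
    int(FlowCondition.HIGH): 2,
}
MERGED_CLASS_NAMES = ("ZERO+LOW", "MEDIUM", "HIGH")


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true, cols = predicted) plus derived metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray          # per class
    recall: np.ndarray
    f1: np.ndarray
    n_test: int
    degenerate: list[str] = field(default_factory=list)  # zero-denominator flags
    class_names: tuple[str, ...] = ()

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_frame(self) -> pd.DataFrame:
        names = self.class_names or tuple(str(i) for i in range(len(self.precision)))
        return pd.DataFrame(
            {
                "class": names,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.confusion.sum(axis=1),
            }
        )


def confusion_matrix(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Count matrix with entry (i, j) = samples of true class i predicted j."""
    t = np.asarray([int(x) for x in true_labels], dtype=int)
    p = np.asarray([int(x) for x in pred_labels], dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label sequences differ in length: {t.size} vs {p.size}")
    if t.size and (t.max() >= n_classes or p.max() >= n_classes or t.min() < 0 or p.min() < 0):
        raise ValueError("labels must lie in [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def report(confusion: np.ndarray, class_names: tuple[str, ...] = ()) -> ClassificationReport:
    """Accuracy and per-class precision/recall/F1 from a confusion matrix.

    Zero-denominator metrics (a class never predicted, never present, or
    with P+R=0) are reported as 0 and flagged in ``degenerate``.
    """
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    n = cm.shape[0]
    diag = np.diag(cm)
    colsum = cm.sum(axis=0)
    rowsum = cm.sum(axis=1)
    degenerate = []
    precision = np.zeros(n)
    recall = np.zeros(n)
    f1 = np.zeros(n)
    for c in range(n):
        if colsum[c] > 0:
            precision[c] = diag[c] / colsum[c]
        else:
            degenerate.append(f"class {c}: no predictions (precision undefined)")
        if rowsum[c] > 0:
            recall[c] = diag[c] / rowsum[c]
        else:
            degenerate.append(f"class {c}: no true samples (recall undefined)")
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            degenerate.append(f"class {c}: P+R=0 (F1 undefined)")
    return ClassificationReport(
        confusion=np.asarray(confusion),
        accuracy=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        n_test=int(total),
        degenerate=degenerate,
        class_names=class_names,
    )


def merge_zero_low(labels) -> np.ndarray:
    """Map 4-class labels to the 3-class merged scheme (ZERO+LOW, MEDIUM, HIGH)."""
    out = []
    for l in labels:
        key = int(l)
        if key not in ZERO_LOW_MERGE_MAP:
            raise ValueError(f"unknown 4-class label {l!r}")
        out.append(ZERO_LOW_MERGE_MAP[key])
    return np.asarray(out, dtype=int)


def run_report(
    true_labels,
    pred_labels,
    variants: tuple[str, ...] = ("four_class",),
    out_dir: str | Path | None = None,
) -> dict[str, ClassificationReport]:
    """Evaluate one prediction set under the requested labelling variants.

    ``variants`` may contain ``"four_class"`` and/or ``"merged"``; an empty
    tuple defaults to the 4-class scheme.  With ``out_dir`` set, writes per-
    variant metric CSVs, confusion-matrix CSVs and heatmap PNGs.
    """
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if not true_labels:
        raise ValueError("no test samples to evaluate")
    if not variants:
        variants = ("four_class",)
    reports: dict[str, ClassificationReport] = {}
    for variant in variants:
        if variant == "four_class":
            names = tuple(c.name for c in FlowCondition)
            cm = confusion_matrix(true_labels, pred_labels, len(FlowCondition))
        elif variant == "merged":
            names = MERGED_CLASS_NAMES
            cm = confusion_matrix(
                merge_zero_low(true_labels), merge_zero_low(pred_labels), len(names)
            )
        else:
            raise ValueError(f"unknown report variant {variant!r}")
        reports[variant] = report(cm, class_names=names)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for variant, rep in reports.items():
            rep.to_frame().to_csv(out_dir / f"metrics_{variant}.csv", index=False)
            pd.DataFrame(
                rep.confusion, index=rep.class_names, columns=rep.class_names
            ).to_csv(out_dir / f"confusion_{variant}.csv")
            _heatmap(rep, out_dir / f"confusion_{variant}.png")
    return reports


def _heatmap(rep: ClassificationReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(rep.confusion, cmap="Blues")
    n = rep.confusion.shape[0]
    ax.set_xticks(range(n), rep.class_names, rotation=45, ha="right")
    ax.set_yticks(range(n), rep.class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(rep.confusion[i, j]), ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
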