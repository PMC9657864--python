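"""Confusion-matrix metrics and the cross-entropy report.

The fall class is positive: a true positive is a correctly detected fall
window. Precision, recall, F1 and accuracy are reported on the 0-100 scale.
A metric whose denominator is zero (e.g. precision with no positive
predictions) is reported as *undefined* (``None``) and flagged, never as 0.

The reported cross entropy is the base-2 form: the summed information (bits)
assigned by the model's predicted probabilities to the true labels. Training
itself minimizes the natural-log binary cross entropy; this function is the
reporting counterpart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    TP: int
    TN: int
    FP: int
    FN: int
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None
    loss_bits: float | None = None
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
            "loss_bits": self.loss_bits,
            "undefined": list(self.undefined),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def to_text(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.2f}"

        lines = [
            "              predicted",
            "              fall  not-fall",
            f"true fall     {self.TP:5d} {self.FN:8d}",
            f"true not-fall {self.FP:5d} {self.TN:8d}",
            "",
            f"precision  {fmt(self.precision)} %",
            f"recall     {fmt(self.recall)} %",
            f"F1-score   {fmt(self.f1)} %",
            f"accuracy   {fmt(self.accuracy)} %",
        ]
        if self.loss_bits is not None:
            lines.append(f"cross-entropy {self.loss_bits:.4f} bits")
        return "\n".join(lines)

    def confusion_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            ",pred_fall,pred_not_fall\n"
            f"true_fall,{self.TP},{self.FN}\n"
            f"true_not_fall,{self.FP},{self.TN}\n"
        )
        return path


def confusion(
    labels_true: np.ndarray, labels_pred: np.ndarray
) -> tuple[int, int, int, int]:
    """Confusion counts (TP, TN, FP, FN) with fall (=1) as the positive class."""
    yt = np.asarray(labels_true).astype(int)
    yp = np.asarray(labels_pred).astype(int)
    if yt.shape != yp.shape or yt.size < 1:
        raise DataError("label vectors must have equal nonzero length")
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    return tp, tn, fp, fn


def precision_recall_f1_accuracy(
    TP: int, TN: int, FP: int, FN: int
) -> tuple[float | None, float | None, float | None, float | None]:
    """The four standard metrics as percentages; None where undefined."""
    precision = 100.0 * TP / (TP + FP) if TP + FP > 0 else None
    recall = 100.0 * TP / (TP + FN) if TP + FN > 0 else None
    f1 = f1_from_precision_recall(precision, recall)
    total = TP + TN + FP + FN
    accuracy = 100.0 * (TP + TN) / total if total > 0 else None
    return precision, recall, f1, accuracy


def f1_from_precision_recall(
    precision: float | None, recall: float | None
) -> float | None:
    """Harmonic mean of precision and recall (both on the % scale)."""
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def cross_entropy_report(
    truth: np.ndarray, scores: np.ndarray, eps: float = 1e-12
) -> float:
    """Total base-2 cross entropy (bits) of the predicted class distribution
    (score, 1-score) against the one-hot truth, summed over samples."""
    y = np.asarray(truth).astype(float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise DataError("truth and scores must have equal length")
    if ((s <= 0) | (s >= 1)).any():
        logger.warning("cross_entropy_report: scores clipped to [%g, 1-%g]", eps, eps)
        s = np.clip(s, eps, 1 - eps)
    return float(-(y * np.log2(s) + (1 - y) * np.log2(1 - s)).sum())


def evaluate(
    labels_true: np.ndarray,
    scores: np.ndarray | None = None,
    labels_pred: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Build a full report from truth plus scores and/or hard labels."""
    if labels_pred is None:
        if scores is None:
            raise DataError("need scores or predicted labels")
        labels_pred = (np.asarray(scores) >= threshold).astype(int)
    tp, tn, fp, fn = confusion(labels_true, labels_pred)
    precision, recall, f1, accuracy = precision_recall_f1_accuracy(tp, tn, fp, fn)
    undefined = tuple(
        name
        for name, v in [
            ("precision", precision), ("recall", recall),
            ("f1", f1), ("accuracy", accuracy),
        ]
        if v is None
    )
    loss = None if scores is None else cross_entropy_report(labels_true, scores)
    return EvalReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        precision=precision, recall=recall, f1=f1, accuracy=accuracy,
        loss_bits=loss, undefined=undefined,
    )
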