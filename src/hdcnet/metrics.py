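"""Pixel-level evaluation of vessel probability maps.

Predictions are thresholded at 0.5 (ties count as background), confusion
counts are accumulated, and the standard segmentation scores are derived:

    SE  = TP / (TP + FN)          (sensitivity / recall)
    SP  = TN / (TN + FP)          (specificity)
    ACC = (TP + TN) / total
    P   = TP / (TP + FP)          (precision)
    F1  = 2 P R / (P + R)

AUC is the area under the ROC curve — equivalently the probability that a
random vessel pixel outranks a random background pixel, ties counted half.
Scores over a test set are pooled globally: counts are summed over all
images before the ratios are formed, and AUC is computed over the pooled
pixels, which is the only way a single AUC per dataset is well defined.
Division-by-zero cases yield NaN and are listed in ``MetricReport.undefined``
rather than being silently reported as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricReport", "aggregate", "auc", "confusion", "scores"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class MetricReport:
    se: float = math.nan
    sp: float = math.nan
    acc: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    auc: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "se": self.se, "sp": self.sp, "acc": self.acc,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "auc": self.auc,
        }


def confusion(prob: np.ndarray, gt: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of ``prob > threshold`` against a binary mask."""
    prob = np.asarray(prob)
    gt = np.asarray(gt)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs gt {gt.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    pred = prob > threshold  # ties -> background
    pos = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & pos)),
        fp=int(np.count_nonzero(pred & ~pos)),
        tn=int(np.count_nonzero(~pred & ~pos)),
        fn=int(np.count_nonzero(~pred & pos)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def scores(c: ConfusionCounts) -> MetricReport:
    """Derive SE/SP/ACC/Precision/Recall/F1 from confusion counts."""
    if min(c.tp, c.fp, c.tn, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undef: list[str] = []
    se = _ratio(c.tp, c.tp + c.fn, "se", undef)
    sp = _ratio(c.tn, c.tn + c.fp, "sp", undef)
    acc = _ratio(c.tp + c.tn, c.total, "acc", undef)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", undef)
    rec = se
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        undef.append("f1")
        f1 = math.nan
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return MetricReport(se=se, sp=sp, acc=acc, precision=prec, recall=rec, f1=f1, undefined=undef)


def auc(prob: np.ndarray, gt: np.ndarray) -> float:
    """Rank-based ROC AUC over flattened scores; NaN if only one class present."""
    prob = np.asarray(prob).ravel()
    gt = np.asarray(gt).ravel().astype(bool)
    if gt.all() or not gt.any():
        return math.nan
    return float(roc_auc_score(gt.astype(int), prob))


def aggregate(pairs: list[tuple[np.ndarray, np.ndarray]], threshold: float = 0.5,
              per_image: bool = False) -> MetricReport:
    """Pool (probability map, ground truth) pairs into one report.

    Default: confusion counts are summed globally across images before the
    ratios are formed, and AUC is computed over all pooled pixels. With
    ``per_image=True`` the threshold metrics and AUC are instead averaged
    over the per-image reports (for sensitivity analyses).
    """
    if not pairs:
        raise ValueError("aggregate() needs at least one evaluated image")
    if per_image:
        reports = []
        for prob, gt in pairs:
            r = scores(confusion(prob, gt, threshold))
            r.auc = auc(prob, gt)
            reports.append(r)
        mean = lambda vals: float(np.nanmean(vals))  # noqa: E731
        out = MetricReport(
            se=mean([r.se for r in reports]), sp=mean([r.sp for r in reports]),
            acc=mean([r.acc for r in reports]),
            precision=mean([r.precision for r in reports]),
            recall=mean([r.recall for r in reports]),
            f1=mean([r.f1 for r in reports]), auc=mean([r.auc for r in reports]),
        )
        return out
    counts = ConfusionCounts()
    for prob, gt in pairs:
        counts = counts + confusion(prob, gt, threshold)
    report = scores(counts)
    all_prob = np.concatenate([np.asarray(p).ravel() for p, _ in pairs])
    all_gt = np.concatenate([np.asarray(g).ravel() for _, g in pairs])
    report.auc = auc(all_prob, all_gt)
    if math.isnan(report.auc):
        report.undefined.append("auc")
    return report
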