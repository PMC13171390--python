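"""Confusion-based and threshold-sweep evaluation inside an FOV mask.

All counts and rates are computed over mask-interior pixels only (the
standard convention for fundus benchmarks, where the black region outside
the camera aperture would otherwise inflate specificity and accuracy).
Rates whose denominator is zero are reported as NaN and listed in the
report's ``undefined`` set rather than silently coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score


class ValidationError(ValueError):
    pass


@dataclass
class MetricsReport:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: float = math.nan
    specificity: float = math.nan
    accuracy: float = math.nan
    dice: float = math.nan
    iou: float = math.nan
    auc_roc: float = math.nan
    pr_curve: list = field(default_factory=list)
    threshold: float = 0.5
    undefined: set = field(default_factory=set)

    def to_dict(self):
        def clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v

        return {
            "tp": int(self.tp), "fp": int(self.fp),
            "tn": int(self.tn), "fn": int(self.fn),
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "accuracy": clean(self.accuracy),
            "dice": clean(self.dice),
            "iou": clean(self.iou),
            "auc_roc": clean(self.auc_roc),
            "threshold": self.threshold,
            "undefined": sorted(self.undefined),
        }

    def to_json(self, **kwargs):
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self):
        d = self.to_dict()
        return "\n".join(f"{k}\t{d[k]}" for k in sorted(d) if k != "undefined")


def _validate(pred_prob, gt, eval_mask):
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    gt = np.asarray(gt)
    eval_mask = (np.ones_like(gt) if eval_mask is None
                 else np.asarray(eval_mask))
    if not (pred_prob.shape == gt.shape == eval_mask.shape):
        raise ValidationError(
            f"shape mismatch: pred {pred_prob.shape}, gt {gt.shape}, "
            f"mask {eval_mask.shape}")
    for name, m in (("gt", gt), ("eval_mask", eval_mask)):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValidationError(f"{name} must be binary")
    keep = eval_mask.astype(bool).ravel()
    return pred_prob.ravel()[keep], gt.ravel()[keep].astype(np.int8)


def confusion(pred_prob, gt, eval_mask=None, threshold: float = 0.5) -> MetricsReport:
    """Pixel confusion counts and derived rates at one threshold.

    Predictions ≥ threshold count as vessel (ties resolve positive).
    """
    scores, labels = _validate(pred_prob, gt, eval_mask)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    rep = MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold)

    def rate(num, den, name):
        if den == 0:
            rep.undefined.add(name)
            return math.nan
        return num / den

    rep.sensitivity = rate(tp, tp + fn, "sensitivity")
    rep.specificity = rate(tn, tn + fp, "specificity")
    rep.accuracy = rate(tp + tn, tp + tn + fp + fn, "accuracy")
    rep.dice = rate(2 * tp, 2 * tp + fp + fn, "dice")
    rep.iou = rate(tp, tp + fp + fn, "iou")
    return rep


def auc_roc(pred_prob, gt, eval_mask=None) -> float:
    """Rank-based (Mann–Whitney, midrank ties) ROC AUC inside the mask.

    Returns NaN when only one class is present.
    """
    scores, labels = _validate(pred_prob, gt, eval_mask)
    if labels.min() == labels.max():
        return math.nan
    return float(roc_auc_score(labels, scores))


def pr_curve(pred_prob, gt, eval_mask=None, n_thresholds: int = 11) -> list:
    """(recall, precision) at evenly spaced thresholds in [0, 1].

    Threshold 0 (the all-positive endpoint) is always included, so the
    curve reaches recall 1.  Precision with no predicted positives is
    reported as 1.0 by convention.
    """
    scores, labels = _validate(pred_prob, gt, eval_mask)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("pr_curve needs at least one positive pixel")
    thresholds = np.unique(np.concatenate([[0.0], np.linspace(0, 1, n_thresholds)]))
    curve = []
    for th in thresholds:
        pred = scores >= th
        tp = int(np.sum(pred & (labels == 1)))
        n_pred = int(pred.sum())
        recall = tp / n_pos
        precision = tp / n_pred if n_pred else 1.0
        curve.append((recall, precision))
    return curve


def evaluate_sample(pred_prob, gt, eval_mask=None, threshold: float = 0.5,
                    n_thresholds: int = 11) -> MetricsReport:
    """Full per-image report: confusion rates, AUC and PR curve."""
    rep = confusion(pred_prob, gt, eval_mask, threshold)
    rep.auc_roc = auc_roc(pred_prob, gt, eval_mask)
    if math.isnan(rep.auc_roc):
        rep.undefined.add("auc_roc")
    try:
        rep.pr_curve = pr_curve(pred_prob, gt, eval_mask, n_thresholds)
    except ValidationError:
        rep.undefined.add("pr_curve")
    return rep


def aggregate(reports) -> MetricsReport:
    """Dataset-level mean of the per-image rates (NaN-aware)."""
    reports = list(reports)
    agg = MetricsReport(
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports),
        threshold=reports[0].threshold if reports else 0.5,
    )
    for name in ("sensitivity", "specificity", "accuracy", "dice", "iou",
                 "auc_roc"):
        vals = [getattr(r, name) for r in reports
                if not math.isnan(getattr(r, name))]
        if vals:
            setattr(agg, name, float(np.mean(vals)))
        else:
            agg.undefined.add(name)
    return agg
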