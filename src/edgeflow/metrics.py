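"""Detection and localization metrics.

Image-level AUROC scores whole-image detection; pixel-level AUROC scores
localization but favours large lesions; the per-region-overlap curve (AUPRO)
averages, at every operating point, the within-region true-positive rate over
the connected anomaly regions — so a 10-pixel lesion counts as much as a
1000-pixel one — against the global false-positive rate, integrated up to an
FPR cap (default 0.3, the community convention) and normalized by the cap.
Pixel precision/recall are reported at a deterministic operating point, by
default the F1-maximizing threshold on the evaluated set.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from sklearn.metrics import precision_recall_curve, roc_auc_score

Array = np.ndarray

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties handled by rank averaging."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def _stack(maps) -> Array:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def aupro(pixel_maps, masks, fpr_cap: float = 0.3) -> float:
    """Per-region-overlap AUC up to `fpr_cap`, normalized by the cap.

    Only images with a nonempty mask contribute; connected regions use
    8-connectivity.  Exact over all distinct score thresholds.
    """
    pixel_maps = _stack(pixel_maps)
    masks = _stack(masks).astype(bool)
    if pixel_maps.shape != masks.shape:
        raise ValueError("pixel_maps and masks shapes differ")
    keep = [i for i in range(len(masks)) if masks[i].any()]
    if not keep:
        raise UndefinedMetricError("AUPRO needs at least one anomalous region")
    pixel_maps = pixel_maps[keep]
    masks = masks[keep]

    region_scores = []
    for m, s in zip(masks, pixel_maps):
        lab, n = ndimage.label(m, structure=EIGHT_CONNECTED)
        for r in range(1, n + 1):
            region_scores.append(np.sort(s[lab == r]))
    neg = np.sort(pixel_maps[~masks])
    if neg.size == 0:
        raise UndefinedMetricError("AUPRO needs negative pixels")

    thresholds = np.unique(pixel_maps)[::-1]  # descending
    # fraction of pixels >= t, per group, vectorized over thresholds
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    pro = np.zeros_like(fpr)
    for rs in region_scores:
        pro += 1.0 - np.searchsorted(rs, thresholds, side="left") / rs.size
    pro /= len(region_scores)

    # prepend the empty operating point and append the all-positive one
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    pro = np.concatenate([[0.0], pro, [1.0]])
    return _integrate_to_cap(fpr, pro, fpr_cap)


def _integrate_to_cap(fpr: Array, pro: Array, cap: float) -> float:
    if not 0.0 < cap <= 1.0:
        raise ValueError("fpr_cap must be in (0, 1]")
    order = np.argsort(fpr, kind="stable")
    fpr, pro = fpr[order], pro[order]
    if fpr[-1] < cap:
        fpr = np.append(fpr, cap)
        pro = np.append(pro, pro[-1])
    if cap not in fpr:
        pro_cap = np.interp(cap, fpr, pro)
        inside = fpr < cap
        fpr = np.append(fpr[inside], cap)
        pro = np.append(pro[inside], pro_cap)
    else:
        inside = fpr <= cap
        fpr, pro = fpr[inside], pro[inside]
    return float(np.trapezoid(pro, fpr) / cap)


def precision_recall_at(
    pixel_maps,
    masks,
    threshold_rule: Union[str, float] = "f1",
) -> Tuple[float, float, float]:
    """(precision, recall, threshold) after binarizing the score maps.

    `threshold_rule` is either a numeric threshold or ``"f1"`` for the
    F1-maximizing threshold on the evaluated set.
    """
    scores = _stack(pixel_maps).ravel()
    truth = _stack(masks).astype(bool).ravel()
    if truth.all() or not truth.any():
        raise UndefinedMetricError("precision/recall needs both pixel classes")
    if isinstance(threshold_rule, str):
        if threshold_rule != "f1":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        prec, rec, thr = precision_recall_curve(truth, scores)
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        best = int(np.argmax(f1[:-1]))
        threshold = float(thr[best])
    else:
        threshold = float(threshold_rule)
    pred = scores >= threshold
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    if tp + fp == 0:
        raise UndefinedMetricError("degenerate threshold: nothing predicted positive")
    return tp / (tp + fp), tp / (tp + fn), threshold


@dataclass
class EvalReport:
    """All reported metrics as fractions in [0, 1]."""

    det_auroc: float
    seg_auroc: float
    seg_aupro: float
    recall: float
    precision: float
    threshold: float
    fpr_cap: float
    seed: int = 0
    config_hash: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path) -> None:
        d = asdict(self)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(d))
            writer.writeheader()
            writer.writerow(d)

    def as_percent(self) -> dict:
        d = asdict(self)
        for k in ("det_auroc", "seg_auroc", "seg_aupro", "recall", "precision"):
            d[k] = 100.0 * d[k]
        return d


def evaluate_maps(
    image_scores,
    image_labels,
    pixel_maps=None,
    masks=None,
    fpr_cap: float = 0.3,
    threshold_rule: Union[str, float] = "f1",
    seed: int = 0,
    config_hash: str = "",
) -> EvalReport:
    """Assemble the full report from scores and (optionally) pixel maps."""
    det = auroc(image_scores, image_labels)
    if pixel_maps is None or masks is None:
        return EvalReport(det, float("nan"), float("nan"), float("nan"),
                          float("nan"), float("nan"), fpr_cap, seed, config_hash)
    flat_masks = _stack(masks).astype(bool)
    seg = auroc(_stack(pixel_maps).ravel(), flat_masks.ravel().astype(int))
    pro = aupro(pixel_maps, masks, fpr_cap=fpr_cap)
    prec, rec, thr = precision_recall_at(pixel_maps, masks, threshold_rule)
    return EvalReport(det, seg, pro, rec, prec, thr, fpr_cap, seed, config_hash)
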