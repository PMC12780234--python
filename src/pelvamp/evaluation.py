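"""Evaluation stack: overlap, detection, correlation and reader agreement.

Covers the study-style metrics: Dice similarity of masks, bounding-box IoU
lesion detection with a permissive 0.01 threshold (lesions are small and
irregular, so any meaningful localization counts), average precision over
confidence-ranked detections, reader sensitivity against a truth table, and
unweighted Cohen's kappa for inter-reader agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.metrics import cohen_kappa_score

from .volume_io import LabelMask

__all__ = [
    "DETECTION_IOU_THRESHOLD",
    "Detection",
    "dsc",
    "iou_boxes",
    "boxes_from_mask",
    "detections_from_probability",
    "match_detections",
    "average_precision",
    "operating_point",
    "sensitivity",
    "cohens_kappa",
    "pearson",
]

#: A prediction counts as a true positive when box IoU >= 0.01.
DETECTION_IOU_THRESHOLD = 0.01

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Detection:
    """An axis-aligned 3D box in half-open voxel coordinates, with confidence."""

    bbox: np.ndarray  # (2, 3): [lo, hi), hi exclusive
    confidence: float = 1.0

    def __post_init__(self) -> None:
        box = np.asarray(self.bbox, dtype=float).reshape(2, 3)
        object.__setattr__(self, "bbox", box)
        if not (box[1] > box[0]).all():
            raise ValueError("box must satisfy lo < hi per axis")


def dsc(a: np.ndarray | LabelMask, b: np.ndarray | LabelMask, *, return_flag: bool = False):
    """Dice similarity 2|A∩B|/(|A|+|B|); both-empty is defined as 1 (flagged)."""
    fa = a.data > 0 if isinstance(a, LabelMask) else np.asarray(a, bool)
    fb = b.data > 0 if isinstance(b, LabelMask) else np.asarray(b, bool)
    if fa.shape != fb.shape:
        raise ValueError("masks must share a shape")
    denom = int(fa.sum()) + int(fb.sum())
    both_empty = denom == 0
    value = 1.0 if both_empty else 2.0 * int((fa & fb).sum()) / denom
    return (value, both_empty) if return_flag else value


def iou_boxes(a: np.ndarray | Detection, b: np.ndarray | Detection) -> float:
    """Volume intersection-over-union of two half-open boxes."""
    ba = (a.bbox if isinstance(a, Detection) else np.asarray(a, float)).reshape(2, 3)
    bb = (b.bbox if isinstance(b, Detection) else np.asarray(b, float)).reshape(2, 3)
    lo = np.maximum(ba[0], bb[0])
    hi = np.minimum(ba[1], bb[1])
    inter = float(np.prod(np.clip(hi - lo, 0, None)))
    vol_a = float(np.prod(ba[1] - ba[0]))
    vol_b = float(np.prod(bb[1] - bb[0]))
    union = vol_a + vol_b - inter
    return inter / union if union > 0 else 0.0


def boxes_from_mask(mask: np.ndarray | LabelMask) -> list[np.ndarray]:
    """Tight half-open boxes of the 26-connected components of a binary mask."""
    fg = mask.data > 0 if isinstance(mask, LabelMask) else np.asarray(mask, bool)
    labeled, n = ndimage.label(fg, structure=_STRUCT_26)
    boxes = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        boxes.append(np.array([[s.start for s in sl], [s.stop for s in sl]], dtype=float))
    return boxes


def detections_from_probability(prob: np.ndarray, threshold: float = 0.5) -> list[Detection]:
    """Boxes of the thresholded probability map, scored by peak probability."""
    fg = prob >= threshold
    labeled, n = ndimage.label(fg, structure=_STRUCT_26)
    out = []
    for i, sl in enumerate(ndimage.find_objects(labeled), start=1):
        if sl is None:
            continue
        conf = float(prob[sl][labeled[sl] == i].max())
        box = np.array([[s.start for s in sl], [s.stop for s in sl]], dtype=float)
        out.append(Detection(box, conf))
    return out


def match_detections(
    preds: Sequence[Detection],
    truths: Sequence[np.ndarray],
    iou_threshold: float = DETECTION_IOU_THRESHOLD,
) -> dict:
    """Greedy confidence-ordered matching of predictions to truth boxes.

    Predictions are visited in descending confidence; each claims the
    unmatched truth of highest IoU if that IoU is at or above the threshold
    (>= 0.01 by default).  Each truth matches at most once; leftover
    predictions are false positives, leftover truths false negatives.

    Returns ``{"labels": per-pred "TP"/"FP" in the input order, "tp", "fp",
    "fn", "matches": pred index -> truth index}``.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    unmatched = set(range(len(truths)))
    labels = ["FP"] * len(preds)
    matches: dict[int, int] = {}
    for i in order:
        best_j, best_iou = None, 0.0
        for j in unmatched:
            v = iou_boxes(preds[i], truths[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= iou_threshold:
            labels[i] = "TP"
            matches[i] = best_j
            unmatched.discard(best_j)
    tp = labels.count("TP")
    return {"labels": labels, "tp": tp, "fp": len(preds) - tp, "fn": len(unmatched), "matches": matches}


def _normalize_sets(preds, truths):
    """Accept single-image lists or per-image lists-of-lists."""
    if len(preds) and isinstance(preds[0], Detection):
        return [list(preds)], [list(truths)]
    return [list(p) for p in preds], [list(t) for t in truths]


def average_precision(
    preds,
    truths,
    iou_threshold: float = DETECTION_IOU_THRESHOLD,
) -> float:
    """All-point interpolated area under the confidence-ranked PR curve.

    Accepts one image's detections/truth boxes, or per-image lists for a
    multi-image evaluation (matching is per image, ranking global).  With a
    single lesion class this is also the mean average precision.  Raises
    ``ValueError`` when there are no truth boxes.
    """
    pred_sets, truth_sets = _normalize_sets(preds, truths)
    n_truth = sum(len(t) for t in truth_sets)
    if n_truth == 0:
        raise ValueError("average precision is undefined without truth boxes")
    scored: list[tuple[float, bool]] = []
    for p_set, t_set in zip(pred_sets, truth_sets):
        res = match_detections(p_set, t_set, iou_threshold)
        for det, lab in zip(p_set, res["labels"]):
            scored.append((det.confidence, lab == "TP"))
    if not scored:
        return 0.0
    scored.sort(key=lambda x: -x[0])
    tp_flags = np.array([tp for _, tp in scored], dtype=float)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1 - tp_flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # Precision envelope (monotone from the right), integrated over recall steps.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def operating_point(preds, truths, confidence_threshold: float,
                    iou_threshold: float = DETECTION_IOU_THRESHOLD) -> tuple[float, float]:
    """(recall, precision) counting only detections above a confidence cut."""
    pred_sets, truth_sets = _normalize_sets(preds, truths)
    tp = fp = fn = 0
    for p_set, t_set in zip(pred_sets, truth_sets):
        kept = [d for d in p_set if d.confidence >= confidence_threshold]
        res = match_detections(kept, t_set, iou_threshold)
        tp += res["tp"]
        fp += res["fp"]
        fn += res["fn"]
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    return recall, precision


def sensitivity(assessments: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-reader recall against a truth table, plus the cross-reader mean.

    ``assessments`` has columns (reader_id, image_id, value); ``truth`` has
    (image_id, value).  Values are binarized (nonzero / non-"none" counts as
    positive).  With zero true positives the recall is undefined and
    reported as NaN with ``defined=False`` — mirroring dashes in reader
    studies without positive samples.
    """
    def positive(v):
        if isinstance(v, str):
            return v.lower() not in {"none", "0", "negative", "absent"}
        return bool(v)

    truth_map = {r.image_id: positive(r.value) for r in truth.itertuples()}
    rows = []
    for reader, grp in assessments.groupby("reader_id"):
        tp = fn = 0
        for r in grp.itertuples():
            if r.image_id not in truth_map or not truth_map[r.image_id]:
                continue
            if positive(r.value):
                tp += 1
            else:
                fn += 1
        defined = (tp + fn) > 0
        rows.append({
            "reader_id": reader,
            "sensitivity": tp / (tp + fn) if defined else float("nan"),
            "defined": defined,
            "n_positive": tp + fn,
        })
    out = pd.DataFrame(rows)
    defined = out[out["defined"]]
    mean_row = {
        "reader_id": "mean",
        "sensitivity": float(defined["sensitivity"].mean()) if len(defined) else float("nan"),
        "defined": bool(len(defined)),
        "n_positive": int(out["n_positive"].sum()),
    }
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)


def cohens_kappa(x: Sequence, y: Sequence, *, return_flag: bool = False):
    """Unweighted Cohen's kappa between two categorical raters.

    Defined as 1 (flagged) when both raters are constant and identical
    (chance agreement is then 1 and the usual formula degenerates).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    labels = np.unique(np.concatenate([x, y]))
    if len(labels) == 1:
        return (1.0, True) if return_flag else 1.0
    value = float(cohen_kappa_score(x, y, labels=labels))
    return (value, False) if return_flag else value


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)
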