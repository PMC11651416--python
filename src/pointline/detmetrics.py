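"""Detection metrics: precision, recall, per-class AP and mAP.

Average precision is the area under the precision-recall curve built by
sweeping the confidence threshold over the ranked detections, with greedy
score-ordered one-to-one matching to ground truths of the same class at a
fixed box-IoU threshold.  All-point interpolation (the monotone precision
envelope) is used, and mAP is the unweighted mean of the per-class APs over
the two trajectory classes.  The conventional operating points are IoU 0.5
(mAP50) and 0.75 (mAP75).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import CATEGORIES
from .geometry import Box, Detection, iou

__all__ = ["PRCurve", "EvalReport", "evaluate_detections", "export_curves"]


@dataclass
class PRCurve:
    """Confidence-ordered precision/recall/F1 points for one class."""

    category: str
    confidence: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    @property
    def f1(self) -> np.ndarray:
        p, r = self.precision, self.recall
        with np.errstate(invalid="ignore", divide="ignore"):
            f = 2 * p * r / (p + r)
        return np.where(p + r > 0, f, 0.0)


@dataclass
class EvalReport:
    ap_per_class: dict[float, dict[str, float]]  # iou_thr -> {class: AP}
    map_per_threshold: dict[float, float]  # iou_thr -> mAP
    curves: dict[str, PRCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ap_per_class": {
                str(t): v for t, v in self.ap_per_class.items()
            },
            "mAP": {str(t): v for t, v in self.map_per_threshold.items()},
        }


def _match_flags(
    dets: Sequence[Detection],
    gt_boxes: Sequence[Box],
    iou_thr: float,
) -> np.ndarray:
    """TP/FP flag per detection (already filtered to one image+class), greedy by score."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = [False] * len(gt_boxes)
    tp = np.zeros(len(dets), dtype=bool)
    for i in order:
        best_j, best_v = -1, iou_thr
        for j, g in enumerate(gt_boxes):
            if used[j]:
                continue
            v = iou(dets[i].box, g)
            if v >= best_v and (best_j == -1 or v > best_v):
                best_j, best_v = j, v
        if best_j >= 0:
            used[best_j] = True
            tp[i] = True
    return tp


def _ap_from_ranked(tp: np.ndarray, n_gt: int) -> tuple[float, np.ndarray, np.ndarray]:
    """All-point-interpolated AP from TP flags ranked by descending score."""
    if n_gt == 0 or tp.size == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - r_prev) * env))
    return ap, precision, recall


def evaluate_detections(
    dets_by_image: Mapping[object, Sequence[Detection]],
    gts_by_image: Mapping[object, Sequence[tuple[Box, object]]],
    iou_thresholds: Sequence[float] = (0.5, 0.75),
) -> EvalReport:
    """Per-class AP and mAP at the given box-IoU matching thresholds.

    ``gts_by_image`` maps each image key to ``(Box, annotation)`` pairs; the
    annotation's ``category`` attribute (or the annotation itself, if it is a
    string) supplies the class.
    """
    ap_per_class: dict[float, dict[str, float]] = {}
    map_per_thr: dict[float, float] = {}
    curves: dict[str, PRCurve] = {}

    def _cat(ann) -> str:
        return ann if isinstance(ann, str) else ann.category

    for thr in iou_thresholds:
        per_class: dict[str, float] = {}
        present: list[str] = []  # classes that enter the mAP mean
        for cat in CATEGORIES:
            scores: list[float] = []
            flags: list[bool] = []
            n_gt = 0
            for key in set(dets_by_image) | set(gts_by_image):
                dets = [d for d in dets_by_image.get(key, []) if d.category == cat]
                gts = [b for b, a in gts_by_image.get(key, []) if _cat(a) == cat]
                n_gt += len(gts)
                tp = _match_flags(dets, gts, thr)
                scores.extend(d.score for d in dets)
                flags.extend(tp.tolist())
            if n_gt == 0:
                if scores:
                    warnings.warn(
                        f"detections present for class {cat!r} with no ground "
                        "truths; AP set to 0"
                    )
                    present.append(cat)
                per_class[cat] = 0.0
                continue
            present.append(cat)
            order = np.argsort(-np.asarray(scores), kind="stable")
            ranked_tp = np.asarray(flags, dtype=bool)[order]
            ap, precision, recall = _ap_from_ranked(ranked_tp, n_gt)
            per_class[cat] = ap
            if thr == min(iou_thresholds):
                conf = np.asarray(scores)[order]
                curves[cat] = PRCurve(cat, conf, precision, recall)
        ap_per_class[thr] = per_class
        map_per_thr[thr] = (
            float(np.mean([per_class[c] for c in present])) if present else 0.0
        )
    return EvalReport(ap_per_class, map_per_thr, curves)


def export_curves(curve: PRCurve, out_path: str | Path) -> tuple[Path, Path]:
    """Write a PR curve as CSV (confidence, precision, recall, F1) plus a PNG plot."""
    if curve.confidence.size == 0:
        raise ValueError("cannot export an empty curve")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["confidence", "precision", "recall", "f1"])
        for c, p, r, f in zip(
            curve.confidence, curve.precision, curve.recall, curve.f1
        ):
            writer.writerow([repr(float(c)), repr(float(p)), repr(float(r)), repr(float(f))])

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(curve.recall, curve.precision, "-o", ms=3)
    axes[0].set_xlabel("recall")
    axes[0].set_ylabel("precision")
    axes[0].set_title(f"PR curve ({curve.category})")
    axes[1].plot(curve.confidence, curve.f1, "-o", ms=3)
    axes[1].set_xlabel("confidence")
    axes[1].set_ylabel("F1")
    axes[1].set_title("F1 vs confidence")
    for ax in axes:
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    png_path = out_path.with_suffix(".png")
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return csv_path, png_path
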