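"""Box overlap measures and the line-distance evaluation geometry.

This module implements the geometric primitives that the trajectory-detection
metric is built from:

* ``iou`` — intersection over union of two axis-aligned boxes;
* ``diou`` — distance-IoU: IoU minus a squared center-distance penalty
  normalised by the squared diagonal of the minimal enclosing box;
* ``point_segment_distance`` / ``point_polyline_distance`` — shortest Euclidean
  distance from a predicted keypoint to a ground-truth trajectory, handling the
  three perpendicular-foot cases (foot before the first endpoint, beyond the
  second, or interior);
* ``line_distance`` (LD) — mean distance of a detection's M keypoints to its
  matched ground-truth polyline;
* ``mean_line_distance`` (mLD) — mean LD over the K matched targets.

All distances are in pixels at whatever resolution the inputs use; mLD scales
linearly with the coordinate scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Box",
    "Detection",
    "SegmentCase",
    "SegmentDistanceCase",
    "MatchTable",
    "LineDistanceReport",
    "iou",
    "diou",
    "point_segment_distance",
    "point_polyline_distance",
    "line_distance",
    "match_detections",
    "mean_line_distance",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with inclusive corners, ``x1 <= x2`` and ``y1 <= y2``."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x1, self.y1, self.x2, self.y2)):
            raise ValueError("box coordinates must be finite")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(
                f"box corners out of order: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def clipped(self, width: float, height: float) -> "Box":
        """Clip the box to the image rectangle [0, width] x [0, height]."""
        return Box(
            min(max(self.x1, 0.0), width),
            min(max(self.y1, 0.0), height),
            min(max(self.x2, 0.0), width),
            min(max(self.y2, 0.0), height),
        )

    def as_xywh(self) -> list[float]:
        return [self.x1, self.y1, self.width, self.height]

    @staticmethod
    def from_xywh(x: float, y: float, w: float, h: float) -> "Box":
        return Box(x, y, x + w, y + h)


@dataclass
class Detection:
    """A predicted target: box + class + confidence + extracted trajectory points."""

    box: Box
    category: str
    score: float
    keypoints: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 2)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when the union has zero area."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def diou(a: Box, b: Box) -> float:
    """Distance-IoU: ``iou(a, b) - rho^2 / c^2``.

    ``rho`` is the distance between box centers and ``c`` the diagonal length of
    the smallest box enclosing both.  Always ``<= iou(a, b)``, with equality iff
    the centers coincide.
    """
    ex = max(a.x2, b.x2) - min(a.x1, b.x1)
    ey = max(a.y2, b.y2) - min(a.y1, b.y1)
    c2 = ex * ex + ey * ey
    if c2 <= 0.0:
        raise ValueError("enclosing box is degenerate: both boxes are the same point")
    (ax, ay), (bx, by) = a.center, b.center
    rho2 = (ax - bx) ** 2 + (ay - by) ** 2
    return iou(a, b) - rho2 / c2


class SegmentCase(enum.Enum):
    """Which of the three perpendicular-foot situations applies."""

    FOOT_BEFORE_A = "foot_before_A"
    FOOT_AFTER_B = "foot_after_B"
    FOOT_INTERIOR = "foot_interior"


@dataclass(frozen=True)
class SegmentDistanceCase:
    case: SegmentCase
    distance: float
    foot: Optional[tuple[float, float]] = None


def point_segment_distance(
    p: Sequence[float], a: Sequence[float], b: Sequence[float]
) -> SegmentDistanceCase:
    """Shortest distance from point ``p`` to segment ``[a, b]``.

    The projection parameter is ``t = <AP, AB> / ||AB||^2``: for ``t <= 0`` the
    closest point is ``a``; for ``t >= 1`` it is ``b``; otherwise it is the
    perpendicular foot ``a + t * (b - a)``.  A zero-length segment degenerates
    to the distance to the single point.
    """
    px, py = float(p[0]), float(p[1])
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    abx, aby = bx - ax, by - ay
    ab2 = abx * abx + aby * aby
    c = (px - ax) * abx + (py - ay) * aby  # <AP, AB>
    if ab2 <= 0.0 or c <= 0.0:
        return SegmentDistanceCase(SegmentCase.FOOT_BEFORE_A, math.hypot(px - ax, py - ay))
    if c >= ab2:  # t = c / ab2 >= 1
        return SegmentDistanceCase(SegmentCase.FOOT_AFTER_B, math.hypot(px - bx, py - by))
    t = c / ab2
    fx, fy = ax + t * abx, ay + t * aby
    return SegmentDistanceCase(
        SegmentCase.FOOT_INTERIOR, math.hypot(px - fx, py - fy), foot=(fx, fy)
    )


def point_polyline_distance(p: Sequence[float], polyline: np.ndarray) -> float:
    """Minimum distance from ``p`` over the consecutive segments of ``polyline``.

    A single-point polyline gives the plain point distance; zero-length
    segments contribute their endpoint distance (which never changes the min).
    """
    pts = np.asarray(polyline, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("polyline must contain at least one point")
    if pts.shape[0] == 1:
        return float(math.hypot(p[0] - pts[0, 0], p[1] - pts[0, 1]))
    # Vectorised three-case segment distance over all G-1 segments.
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ap = np.asarray(p, dtype=float) - a
    c = np.einsum("ij,ij->i", ap, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(ab2 > 0.0, c / np.where(ab2 > 0.0, ab2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.hypot(p[0] - foot[:, 0], p[1] - foot[:, 1])
    return float(d.min())


def line_distance(pred_points: np.ndarray, gt_polyline: np.ndarray) -> float:
    """LD: mean distance of M predicted keypoints to the ground-truth polyline."""
    preds = np.asarray(pred_points, dtype=float).reshape(-1, 2)
    if preds.shape[0] == 0:
        raise ValueError("a target with no predicted keypoints has no line distance")
    return float(
        np.mean([point_polyline_distance(p, gt_polyline) for p in preds])
    )


@dataclass
class MatchTable:
    """One-to-one detection/ground-truth correspondence at a box-IoU threshold."""

    pairs: list[tuple[int, int]]
    unmatched_detections: list[int]
    unmatched_ground_truths: list[int]


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[tuple[Box, object]],
    iou_threshold: float = 0.5,
) -> MatchTable:
    """Greedy score-ordered one-to-one matching of detections to ground truths.

    Detections are visited in descending score order (ties broken by input
    index) and paired with the unmatched same-category ground truth of highest
    box IoU, provided that IoU reaches ``iou_threshold``.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    gt_used = [False] * len(gts)
    pairs: list[tuple[int, int]] = []
    unmatched_dets: list[int] = []
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j, (gt_box, gt_ann) in enumerate(gts):
            if gt_used[j]:
                continue
            cat = getattr(gt_ann, "category", None)
            if cat is not None and cat != det.category:
                continue
            v = iou(det.box, gt_box)
            if v > best_iou or (v == best_iou and v > 0.0 and best_j == -1):
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            gt_used[best_j] = True
            pairs.append((i, best_j))
        else:
            unmatched_dets.append(i)
    unmatched_gts = [j for j, used in enumerate(gt_used) if not used]
    pairs.sort()
    return MatchTable(pairs, sorted(unmatched_dets), unmatched_gts)


@dataclass
class LineDistanceReport:
    """Per-target LD values and their mean (mLD) over the K matched targets."""

    per_target_ld: list[float]
    mld: Optional[float]
    n_matched: int
    per_target_m: list[int]
    per_target_g: list[int]
    match_table: Optional[MatchTable] = None

    def to_dict(self) -> dict:
        return {
            "mld": self.mld,
            "n_matched": self.n_matched,
            "per_target_ld": self.per_target_ld,
            "per_target_m": self.per_target_m,
            "per_target_g": self.per_target_g,
        }


def mean_line_distance(
    matches: MatchTable,
    dets: Sequence[Detection],
    gts: Sequence[tuple[Box, object]],
) -> LineDistanceReport:
    """mLD: arithmetic mean of LD over matched detection/ground-truth pairs.

    Matched detections with zero extracted keypoints contribute no LD (they are
    dropped from K).  With no contributing pairs the mLD is reported as absent.
    """
    lds: list[float] = []
    ms: list[int] = []
    gs: list[int] = []
    for det_idx, gt_idx in matches.pairs:
        det = dets[det_idx]
        gt_ann = gts[gt_idx][1]
        gt_points = np.asarray(getattr(gt_ann, "points", gt_ann), dtype=float).reshape(-1, 2)
        if det.keypoints.shape[0] == 0:
            continue
        lds.append(line_distance(det.keypoints, gt_points))
        ms.append(int(det.keypoints.shape[0]))
        gs.append(int(gt_points.shape[0]))
    mld = float(np.mean(lds)) if lds else None
    return LineDistanceReport(lds, mld, len(lds), ms, gs, matches)
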