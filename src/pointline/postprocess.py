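"""From raw detector output to final trajectory predictions.

Two steps, in this order:

1. box-level suppression (:mod:`pointline.suppression`) removes or down-weights
   redundant detections;
2. per surviving detection, the single heatmap is reduced to discrete peaks —
   strict 8-neighbourhood local maxima above a value threshold, greedily
   thinned so kept peaks are at least ``min_separation`` cells apart
   (Chebyshev) — and each kept cell center is mapped back to image coordinates
   through the inverse of the box-to-grid affine map.

The predicted keypoints are deliberately left unordered: the evaluation metric
measures point-to-polyline distance and needs no ordering of predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import CATEGORIES
from .geometry import Box, Detection
from .heatmaps import Heatmap
from .suppression import ScoredBox, hard_nms, soft_nms

__all__ = ["Peak", "PeakConfig", "NMSConfig", "extract_keypoints", "detections_to_predictions"]


@dataclass(frozen=True)
class Peak:
    grid_cell: tuple[int, int]  # (row, col)
    value: float
    image_xy: tuple[float, float]


@dataclass(frozen=True)
class PeakConfig:
    value_threshold: float = 0.3
    min_separation: int = 2  # grid cells, Chebyshev
    max_points: int = 32


@dataclass(frozen=True)
class NMSConfig:
    mode: str = "soft_diou"  # hard | soft | soft_diou
    iou_threshold: float = 0.5
    sigma: float = 0.5
    score_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft", "soft_diou"):
            raise ValueError(f"unknown nms mode {self.mode!r}")


def extract_keypoints(
    hm: Heatmap,
    box: Box | None = None,
    value_threshold: float = 0.3,
    min_separation: int = 2,
    max_points: int = 32,
) -> list[Peak]:
    """Extract trajectory keypoints from a single instance heatmap.

    Candidates are cells that are >= all 8 neighbours and above
    ``value_threshold``; plateau ties go to the lexicographically smallest
    (row, col).  Candidates are then kept greedily in descending value order
    (ties again lexicographic), skipping any within ``min_separation`` cells of
    an already-kept peak, up to ``max_points``.
    """
    if not 0.0 <= value_threshold <= 1.0:
        raise ValueError("value_threshold must be in [0, 1]")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    box = box if box is not None else hm.box
    grid = np.asarray(hm.grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("heatmap grid must be 2-D with size >= 2")
    h, w = grid.shape
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = grid

    is_max = np.ones((h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            if dr < 0 or (dr == 0 and dc < 0):
                # neighbour precedes the cell lexicographically: cell must be
                # strictly greater to win the plateau tie
                is_max &= grid > neigh
            else:
                is_max &= grid >= neigh
    is_max &= grid >= value_threshold

    rows, cols = np.nonzero(is_max)
    cand = sorted(
        zip(rows.tolist(), cols.tolist()),
        key=lambda rc: (-grid[rc[0], rc[1]], rc[0], rc[1]),
    )
    kept: list[tuple[int, int]] = []
    for r, c in cand:
        if len(kept) >= max_points:
            break
        if any(max(abs(r - kr), abs(c - kc)) < min_separation for kr, kc in kept):
            continue
        kept.append((r, c))

    peaks = []
    for r, c in kept:
        x = box.x1 + (c + 0.5) / grid.shape[1] * box.width
        y = box.y1 + (r + 0.5) / grid.shape[0] * box.height
        peaks.append(Peak((r, c), float(grid[r, c]), (float(x), float(y))))
    return peaks


def detections_to_predictions(
    raw: Sequence[tuple[Box, str, float, Heatmap]],
    nms: NMSConfig = NMSConfig(),
    peaks: PeakConfig = PeakConfig(),
) -> list[Detection]:
    """Suppress at box level first, then extract keypoints for survivors only."""
    class_ids = {c: i for i, c in enumerate(CATEGORIES)}
    scored = [
        ScoredBox(box, score, class_ids[cat]) for box, cat, score, _hm in raw
    ]
    if nms.mode == "hard":
        kept = hard_nms(scored, nms.iou_threshold)
    else:
        overlap = "diou" if nms.mode == "soft_diou" else "iou"
        kept = soft_nms(scored, nms.sigma, nms.score_floor, overlap)
    # map survivors back to their raw entries (box identity is unique enough:
    # match on (box corners, class); scores may have been decayed)
    index = {}
    for i, (box, cat, score, _hm) in enumerate(raw):
        index.setdefault((box.x1, box.y1, box.x2, box.y2, class_ids[cat]), []).append(i)
    out: list[Detection] = []
    for sb in kept:
        key = (sb.box.x1, sb.box.y1, sb.box.x2, sb.box.y2, sb.class_id)
        i = index[key].pop(0)
        box, cat, _score, hm = raw[i]
        plist = extract_keypoints(
            hm, box, peaks.value_threshold, peaks.min_separation, peaks.max_points
        )
        kps = np.array([p.image_xy for p in plist]).reshape(-1, 2)
        out.append(Detection(box, cat, sb.score, kps))
    return out
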