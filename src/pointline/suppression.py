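"""Non-maximum suppression variants used at the box level.

Three modes are provided, matching the ``nms.mode`` config keys:

* ``hard`` — classical greedy NMS: keep the top-scoring box, drop every box
  whose IoU with it exceeds a threshold;
* ``soft`` — Soft-NMS with Gaussian score decay instead of deletion;
* ``soft_diou`` — Soft-NMS where the overlap fed to the decay is the
  distance-IoU, so that of two equally overlapping boxes the one whose center
  is further from the keeper decays less.  This is the combination intended to
  survive dense occlusion between neighbouring leaves.

Suppression is always class-wise: a leaf never suppresses a stalk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .geometry import Box, diou, iou

__all__ = ["ScoredBox", "hard_nms", "soft_nms"]


@dataclass(frozen=True)
class ScoredBox:
    box: Box
    score: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


def _overlap_fn(name: str) -> Callable[[Box, Box], float]:
    if name == "iou":
        return iou
    if name == "diou":
        return diou
    raise ValueError(f"unknown overlap function {name!r}; expected 'iou' or 'diou'")


def hard_nms(dets: Sequence[ScoredBox], overlap_threshold: float) -> list[ScoredBox]:
    """Greedy class-wise NMS; returns survivors sorted by descending score.

    Boxes with IoU strictly greater than ``overlap_threshold`` against an
    already-kept higher-scoring box of the same class are discarded.
    """
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in [0, 1]")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[ScoredBox] = []
    for i in order:
        d = dets[i]
        if any(
            k.class_id == d.class_id and iou(k.box, d.box) > overlap_threshold
            for k in kept
        ):
            continue
        kept.append(d)
    return kept


def soft_nms(
    dets: Sequence[ScoredBox],
    sigma: float = 0.5,
    score_floor: float = 0.001,
    overlap: str = "iou",
) -> list[ScoredBox]:
    """Soft-NMS with Gaussian score decay ``s <- s * exp(-o^2 / sigma)``.

    ``o`` is the overlap with the current keeper, clamped to ``max(o, 0)`` so a
    negative distance-IoU (far-apart boxes) decays nothing.  Boxes whose score
    falls below ``score_floor`` are removed; survivors keep their decayed
    scores and are returned in descending-score order of selection.
    """
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= score_floor < 1.0:
        raise ValueError("score_floor must be in [0, 1)")
    ov = _overlap_fn(overlap)
    remaining = sorted(
        (replace(d) for d in dets), key=lambda d: -d.score
    )
    kept: list[ScoredBox] = []
    while remaining:
        # stable argmax: highest score, earliest on ties
        best = max(range(len(remaining)), key=lambda i: (remaining[i].score, -i))
        keeper = remaining.pop(best)
        kept.append(keeper)
        decayed: list[ScoredBox] = []
        for d in remaining:
            if d.class_id != keeper.class_id:
                decayed.append(d)
                continue
            o = max(ov(keeper.box, d.box), 0.0)
            s = d.score * math.exp(-(o * o) / sigma)
            if s >= score_floor:
                decayed.append(replace(d, score=s))
        remaining = decayed
    return kept
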