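"""The Point-Line Net model.

A two-stage detector in the Faster R-CNN mould — FPN backbone, region proposal
network, RoIAlign box head — extended with a lightweight keypoint branch that
predicts *one* heatmap per detected instance in which every trajectory point
appears as a peak.  The branch shares the RPN's proposals with the box branch;
no per-keypoint channel exists because the trajectory points are positionally
interchangeable along the leaf midrib or stalk axis.

The ``resnet*_fpn`` / ``mobilenet_fpn`` profiles mirror the capacity presets a
GPU deployment would use; the ``tiny_fpn`` profile (narrow trunk, two pyramid
levels) is the CPU-scale configuration exercised by the test-suite and the
synthetic end-to-end run.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .annotations import (
    AnnotatedImage,
    CATEGORIES,
    densify_polyline,
    derive_bbox,
    subsample_equal_interval,
)
from .geometry import Box, iou
from .heatmaps import Heatmap, render_target_heatmap

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingSample",
    "PointLineNet",
    "build_model",
    "render_target_heatmap",
    "keypoint_loss",
    "augment",
    "prepare_sample",
    "train",
    "learning_rate_at",
    "save_checkpoint",
    "load_checkpoint",
]

# backbone profile -> trunk/fpn hyperparameters
_BACKBONES = {
    "tiny_fpn": dict(stem=8, widths=(16, 32, 32), blocks=(1, 1, 1),
                     residual=False, fpn_channels=32, fpn_levels=2),
    "mobilenet_fpn": dict(stem=16, widths=(24, 48, 96, 160), blocks=(1, 2, 3, 2),
                          residual=False, fpn_channels=64, fpn_levels=4),
    "resnet50_fpn": dict(stem=64, widths=(64, 128, 256, 512), blocks=(3, 4, 6, 3),
                         residual=True, fpn_channels=256, fpn_levels=4),
    "resnet101_fpn": dict(stem=64, widths=(64, 128, 256, 512), blocks=(3, 4, 23, 3),
                          residual=True, fpn_channels=256, fpn_levels=4),
}
_FULL_PROFILES = ("resnet101_fpn", "resnet50_fpn", "mobilenet_fpn")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and proposal-budget configuration.

    Defaults are the full-scale profile: ResNet101+FPN trunk, five anchor
    areas (32^2 ... 512^2), 4000/2000 proposals kept before/after RPN NMS, and
    RoIAlign output size 14.
    """

    backbone: str = "resnet101_fpn"
    anchor_areas: tuple[float, ...] = (32**2, 64**2, 128**2, 256**2, 512**2)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_pre_nms: int = 4000
    rpn_post_nms: int = 2000
    roi_align_size: int = 14
    heatmap_size: int = 56
    num_classes: int = 3  # background + leaf + stalk
    sigma_hm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; known: {sorted(_BACKBONES)}"
            )
        if self.backbone in _FULL_PROFILES and len(self.anchor_areas) != 5:
            raise ValueError(
                f"profile {self.backbone!r} uses 5 anchor areas, got {len(self.anchor_areas)}"
            )
        if not self.rpn_pre_nms >= self.rpn_post_nms > 0:
            raise ValueError("need rpn_pre_nms >= rpn_post_nms > 0")
        if self.roi_align_size <= 0 or self.heatmap_size < 2:
            raise ValueError("invalid RoIAlign/heatmap size")

    @staticmethod
    def full_profile(**overrides) -> "ModelConfig":
        return ModelConfig(**overrides)

    @staticmethod
    def tiny_profile(**overrides) -> "ModelConfig":
        """CPU-scale profile for small synthetic scenes (~256 px)."""
        defaults = dict(
            backbone="tiny_fpn",
            anchor_areas=(24.0**2, 48.0**2, 96.0**2),
            anchor_ratios=(0.25, 0.5, 1.0, 2.0, 4.0),
            rpn_pre_nms=600,
            rpn_post_nms=128,
            roi_align_size=7,
            heatmap_size=28,
        )
        defaults.update(overrides)
        return ModelConfig(**defaults)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults follow the full-scale training recipe
    (SGD + momentum, lr 1e-3, weight decay 1e-4, StepLR x0.66 every 10 epochs,
    200 epochs, random flip + colour jitter)."""

    epochs: int = 200
    base_lr: float = 1e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9
    lr_step: int = 10
    lr_gamma: float = 0.66
    seed: int = 0
    flip_prob: float = 0.5
    color_jitter: bool = True

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0.0 < self.lr_gamma < 1.0:
            raise ValueError("lr_gamma must be in (0, 1)")
        if self.epochs < 1 or self.lr_step < 1:
            raise ValueError("epochs and lr_step must be >= 1")


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """StepLR: ``base_lr * gamma ** floor(epoch / step)``."""
    return cfg.base_lr * cfg.lr_gamma ** (epoch // cfg.lr_step)


# ------------------------------------------------------------------ backbone


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        self.conv = nn.Conv2d(cin, cout, 3, stride, 1, rng)

    def __call__(self, x):
        return nn.relu(self.conv(x))


class _ResidualBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, rng)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng)
        self.proj = (
            nn.Conv2d(cin, cout, 1, stride, 0, rng) if (stride != 1 or cin != cout) else None
        )

    def __call__(self, x):
        y = self.conv2(nn.relu(self.conv1(x)))
        skip = self.proj(x) if self.proj is not None else x
        return nn.relu(nn.add(y, skip))


class _FPNBackbone(nn.Module):
    """Bottom-up trunk + top-down pyramid; returns the finest-to-coarsest maps."""

    def __init__(self, profile: dict, rng: np.random.Generator):
        self.stem = nn.Conv2d(3, profile["stem"], 3, 2, 1, rng)
        block = _ResidualBlock if profile["residual"] else _ConvBlock
        self.stages: list[list[nn.Module]] = []
        cin = profile["stem"]
        for width, depth in zip(profile["widths"], profile["blocks"]):
            stage = [block(cin, width, 2, rng)]
            stage += [block(width, width, 1, rng) for _ in range(depth - 1)]
            self.stages.append(stage)
            cin = width
        self.n_levels = profile["fpn_levels"]
        c = profile["fpn_channels"]
        used = profile["widths"][-self.n_levels :]
        self.laterals = [nn.Conv2d(w, c, 1, 1, 0, rng) for w in used]
        self.smooth = [nn.Conv2d(c, c, 3, 1, 1, rng) for _ in used]
        self.out_channels = c
        # stride of the finest used stage: stem /2 then one /2 per stage
        first_used = len(profile["widths"]) - self.n_levels
        self.strides = [2 ** (2 + first_used + i) for i in range(self.n_levels)]

    def parameters(self):
        params = list(self.stem.parameters())
        for stage in self.stages:
            for b in stage:
                params.extend(b.parameters())
        for m in self.laterals + self.smooth:
            params.extend(m.parameters())
        return params

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        y = nn.relu(self.stem(x))
        feats = []
        for stage in self.stages:
            for b in stage:
                y = b(y)
            feats.append(y)
        used = feats[-self.n_levels :]
        # top-down pathway
        pyramid: list[Optional[nn.Tensor]] = [None] * self.n_levels
        prev = None
        for i in range(self.n_levels - 1, -1, -1):
            lat = self.laterals[i](used[i])
            if prev is not None:
                lat = nn.add(lat, nn.upsample2x(prev))
            prev = lat
            pyramid[i] = self.smooth[i](lat)
        return pyramid  # finest (smallest stride) first


# ---------------------------------------------------------------- box utils


def _box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) corner-format box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def _encode(rois: np.ndarray, gts: np.ndarray) -> np.ndarray:
    rw = np.maximum(rois[:, 2] - rois[:, 0], 1e-3)
    rh = np.maximum(rois[:, 3] - rois[:, 1], 1e-3)
    rx = rois[:, 0] + 0.5 * rw
    ry = rois[:, 1] + 0.5 * rh
    gw = np.maximum(gts[:, 2] - gts[:, 0], 1e-3)
    gh = np.maximum(gts[:, 3] - gts[:, 1], 1e-3)
    gx = gts[:, 0] + 0.5 * gw
    gy = gts[:, 1] + 0.5 * gh
    return np.stack(
        [(gx - rx) / rw, (gy - ry) / rh, np.log(gw / rw), np.log(gh / rh)], axis=1
    )


def _decode(rois: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    rw = np.maximum(rois[:, 2] - rois[:, 0], 1e-3)
    rh = np.maximum(rois[:, 3] - rois[:, 1], 1e-3)
    rx = rois[:, 0] + 0.5 * rw
    ry = rois[:, 1] + 0.5 * rh
    dx, dy, dw, dh = deltas.T
    cx = rx + dx * rw
    cy = ry + dy * rh
    w = rw * np.exp(np.clip(dw, -4.0, 4.0))
    h = rh * np.exp(np.clip(dh, -4.0, 4.0))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _nms_array(boxes: np.ndarray, scores: np.ndarray, thr: float, max_keep: int) -> np.ndarray:
    """Fast greedy IoU NMS on plain arrays (proposal filtering)."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size > 0 and len(keep) < max_keep:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = _box_iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious <= thr]
    return np.asarray(keep, dtype=int)


# ------------------------------------------------------------------- model


@dataclass
class TrainingSample:
    """One preprocessed image: pixels + derived boxes, labels and keypoints."""

    image: np.ndarray  # (H, W, 3) uint8
    boxes: np.ndarray  # (N, 4) corner format
    labels: np.ndarray  # (N,) in {1: leaf, 2: stalk}
    keypoints: list[np.ndarray] = field(default_factory=list)  # per-instance (K, 2)


def prepare_sample(
    image: np.ndarray,
    ann: AnnotatedImage,
    offset: float = 20.0,
    ratio: float = 0.3,
    spacing: float = 5.0,
) -> TrainingSample:
    """Derive detection boxes and subsampled ground-truth keypoints."""
    boxes, labels, kps = [], [], []
    for a in ann.annotations:
        box = derive_bbox(a, offset, (ann.width, ann.height))
        boxes.append([box.x1, box.y1, box.x2, box.y2])
        labels.append(1 + CATEGORIES.index(a.category))
        kps.append(subsample_equal_interval(densify_polyline(a.points, spacing), ratio))
    return TrainingSample(
        image=image,
        boxes=np.asarray(boxes, dtype=float).reshape(-1, 4),
        labels=np.asarray(labels, dtype=int),
        keypoints=kps,
    )


class PointLineNet(nn.Module):
    """Two-stage detector with the single-heatmap keypoint branch."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        profile = _BACKBONES[cfg.backbone]
        self.backbone = _FPNBackbone(profile, rng)
        c = self.backbone.out_channels
        L = self.backbone.n_levels
        # distribute anchor areas over pyramid levels, finest level first
        K = len(cfg.anchor_areas)
        self.level_areas: list[list[float]] = [[] for _ in range(L)]
        for i, area in enumerate(sorted(cfg.anchor_areas)):
            self.level_areas[min(i * L // K, L - 1)].append(area)
        for lv in self.level_areas:
            if not lv:
                lv.append(sorted(cfg.anchor_areas)[0])
        self.rpn_conv = nn.Conv2d(c, c, 3, 1, 1, rng)
        self.rpn_obj = [
            nn.Conv2d(c, len(a) * len(cfg.anchor_ratios), 1, 1, 0, rng)
            for a in self.level_areas
        ]
        self.rpn_reg = [
            nn.Conv2d(c, 4 * len(a) * len(cfg.anchor_ratios), 1, 1, 0, rng)
            for a in self.level_areas
        ]
        s = cfg.roi_align_size
        self.fc1 = nn.Linear(c * s * s, 256, rng)
        self.cls_head = nn.Linear(256, cfg.num_classes, rng)
        self.reg_head = nn.Linear(256, 4, rng)
        hm = cfg.heatmap_size
        if hm % 2 != 0:
            raise ValueError("heatmap_size must be even (aligned at half resolution)")
        self.kp_align = hm // 2
        self.kp_conv1 = nn.Conv2d(c, 32, 3, 1, 1, rng)
        self.kp_conv2 = nn.Conv2d(32, 32, 3, 1, 1, rng)
        self.kp_out = nn.Conv2d(32, 1, 1, 1, 0, rng)
        self._anchor_cache: dict = {}

    # -- anchors -----------------------------------------------------------

    def _anchors_for(self, level: int, fh: int, fw: int) -> np.ndarray:
        key = (level, fh, fw)
        if key in self._anchor_cache:
            return self._anchor_cache[key]
        stride = self.backbone.strides[level]
        shapes = []
        for area in self.level_areas[level]:
            for r in self.cfg.anchor_ratios:
                w = math.sqrt(area / r)
                h = math.sqrt(area * r)
                shapes.append((w, h))
        cx = (np.arange(fw) + 0.5) * stride
        cy = (np.arange(fh) + 0.5) * stride
        anchors = np.empty((len(shapes), fh, fw, 4))
        for a, (w, h) in enumerate(shapes):
            anchors[a, :, :, 0] = cx[None, :] - w / 2
            anchors[a, :, :, 1] = cy[:, None] - h / 2
            anchors[a, :, :, 2] = cx[None, :] + w / 2
            anchors[a, :, :, 3] = cy[:, None] + h / 2
        flat = anchors.reshape(-1, 4)
        self._anchor_cache[key] = flat
        return flat

    # -- forward pieces ----------------------------------------------------

    def _rpn_forward(self, pyramid):
        """Per-level objectness logits and box deltas, flattened anchor-major."""
        obj_t, reg_t, anchors = [], [], []
        for lv, feat in enumerate(pyramid):
            shared = nn.relu(self.rpn_conv(feat))
            _, _, fh, fw = feat.data.shape
            a = len(self.level_areas[lv]) * len(self.cfg.anchor_ratios)
            obj = nn.reshape(self.rpn_obj[lv](shared), (a * fh * fw,))
            reg = nn.reshape(self.rpn_reg[lv](shared), (a, 4, fh, fw))
            reg = nn.reshape(nn.permute(reg, (0, 2, 3, 1)), (a * fh * fw, 4))
            obj_t.append(obj)
            reg_t.append(reg)
            anchors.append(self._anchors_for(lv, fh, fw))
        return nn.concat(obj_t), nn.concat(reg_t), np.concatenate(anchors)

    def _proposals(self, obj_logits: np.ndarray, deltas: np.ndarray,
                   anchors: np.ndarray, image_hw) -> np.ndarray:
        h, w = image_hw
        scores = obj_logits
        k = min(self.cfg.rpn_pre_nms, scores.size)
        top = np.argpartition(-scores, k - 1)[:k]
        boxes = _decode(anchors[top], deltas[top])
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ok = (boxes[:, 2] - boxes[:, 0] > 2) & (boxes[:, 3] - boxes[:, 1] > 2)
        boxes, sc = boxes[ok], scores[top][ok]
        keep = _nms_array(boxes, sc, 0.7, self.cfg.rpn_post_nms)
        return boxes[keep]

    def _assign_roi_level(self, rois: np.ndarray) -> np.ndarray:
        """FPN level per RoI by scale (k0 + log2(sqrt(wh)/canonical))."""
        L = self.backbone.n_levels
        if L == 1:
            return np.zeros(len(rois), dtype=int)
        scale = np.sqrt(
            np.maximum((rois[:, 2] - rois[:, 0]) * (rois[:, 3] - rois[:, 1]), 1e-6)
        )
        canonical = 8.0 * self.backbone.strides[0]
        lv = np.floor(np.log2(np.maximum(scale, 1e-6) / canonical)).astype(int) + 1
        return np.clip(lv, 0, L - 1)

    def _roi_features(self, pyramid, rois: np.ndarray, out_size: int) -> nn.Tensor:
        levels = self._assign_roi_level(rois)
        parts, order = [], []
        for lv in range(self.backbone.n_levels):
            idx = np.nonzero(levels == lv)[0]
            if idx.size == 0:
                continue
            parts.append(
                nn.roi_align(pyramid[lv], rois[idx], out_size, self.backbone.strides[lv])
            )
            order.extend(idx.tolist())
        feats = parts[0] if len(parts) == 1 else nn.concat(parts, axis=0)
        inv = np.argsort(np.asarray(order))
        return nn.gather_rows(feats, inv)

    def _box_head(self, pyramid, rois: np.ndarray):
        feats = self._roi_features(pyramid, rois, self.cfg.roi_align_size)
        flat = nn.reshape(feats, (len(rois), -1))
        hidden = nn.relu(self.fc1(flat))
        return self.cls_head(hidden), self.reg_head(hidden)

    def _kp_head(self, pyramid, rois: np.ndarray) -> nn.Tensor:
        feats = self._roi_features(pyramid, rois, self.kp_align)
        y = nn.relu(self.kp_conv1(feats))
        y = nn.relu(self.kp_conv2(y))
        y = nn.upsample2x(y)
        return self.kp_out(y)  # (R, 1, hm, hm) logits

    # -- training ----------------------------------------------------------

    def losses(self, sample: TrainingSample, rng: np.random.Generator) -> dict[str, nn.Tensor]:
        """RPN + box-head + keypoint-branch losses for one image."""
        img = sample.image.astype(np.float32) / 255.0 - 0.5
        x = nn.Tensor(np.ascontiguousarray(img.transpose(2, 0, 1))[None])
        h, w = sample.image.shape[:2]
        pyramid = self.backbone(x)
        obj, reg, anchors = self._rpn_forward(pyramid)
        gt = sample.boxes

        out: dict[str, nn.Tensor] = {}
        # --- RPN targets: IoU >= 0.6 (or per-gt argmax) positive, < 0.3 negative
        iou_m = _box_iou_matrix(anchors, gt)
        max_iou = iou_m.max(axis=1) if gt.size else np.zeros(len(anchors))
        argmax = iou_m.argmax(axis=1) if gt.size else np.zeros(len(anchors), dtype=int)
        pos_mask = max_iou >= 0.6
        if gt.size:
            pos_mask[iou_m.argmax(axis=0)] = True
        neg_mask = max_iou < 0.3
        pos_idx = np.nonzero(pos_mask)[0]
        neg_idx = np.nonzero(neg_mask & ~pos_mask)[0]
        n_pos = min(len(pos_idx), 64)
        n_neg = min(len(neg_idx), 128 - n_pos)
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False) if n_pos else pos_idx[:0]
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False) if n_neg else neg_idx[:0]
        sel = np.concatenate([pos_idx, neg_idx])
        targets = np.zeros(len(sel), dtype=np.float32)
        targets[: len(pos_idx)] = 1.0
        out["rpn_obj"] = nn.sigmoid_bce_loss(nn.gather_rows(obj, sel), targets)
        if len(pos_idx):
            reg_t = _encode(anchors[pos_idx], gt[argmax[pos_idx]])
            out["rpn_box"] = nn.smooth_l1_loss(
                nn.gather_rows(reg, pos_idx), reg_t, beta=1.0 / 9.0, norm=len(sel)
            )

        # --- proposals (no grad through boxes) + gt boxes as extra rois
        props = self._proposals(obj.data, reg.data, anchors, (h, w))
        rois = np.concatenate([props, gt]) if gt.size else props
        if len(rois) == 0:
            return out
        iou_r = _box_iou_matrix(rois, gt)
        max_r = iou_r.max(axis=1) if gt.size else np.zeros(len(rois))
        arg_r = iou_r.argmax(axis=1) if gt.size else np.zeros(len(rois), dtype=int)
        pos_r = np.nonzero(max_r >= 0.5)[0]
        neg_r = np.nonzero(max_r < 0.5)[0]
        n_pos = min(len(pos_r), 16)
        n_neg = min(len(neg_r), 48 - n_pos)
        pos_r = rng.choice(pos_r, size=n_pos, replace=False) if n_pos else pos_r[:0]
        neg_r = rng.choice(neg_r, size=n_neg, replace=False) if n_neg else neg_r[:0]
        sel_r = np.concatenate([pos_r, neg_r]).astype(int)
        if len(sel_r) == 0:
            return out
        labels = np.zeros(len(sel_r), dtype=int)
        labels[: len(pos_r)] = sample.labels[arg_r[pos_r]]
        cls_logits, reg_out = self._box_head(pyramid, rois[sel_r])
        out["cls"] = nn.softmax_ce_loss(cls_logits, labels)
        if len(pos_r):
            reg_t = _encode(rois[pos_r], gt[arg_r[pos_r]])
            out["box"] = nn.smooth_l1_loss(
                nn.gather_rows(reg_out, np.arange(len(pos_r))), reg_t, norm=len(sel_r)
            )

        # --- keypoint branch on positive rois (same proposals as box branch)
        if len(pos_r):
            kp_rois = pos_r[: 8]
            logits = self._kp_head(pyramid, rois[kp_rois])
            hm = self.cfg.heatmap_size
            tgt = np.zeros((len(kp_rois), 1, hm, hm), dtype=np.float32)
            for i, ri in enumerate(kp_rois):
                b = rois[ri]
                kps = sample.keypoints[arg_r[ri]]
                target_hm = render_target_heatmap(
                    kps, Box(*b), hm, self.cfg.sigma_hm
                )
                tgt[i, 0] = target_hm.grid
            out["kp"] = nn.sigmoid_bce_loss(logits, tgt, weight=4.0)
        return out

    # -- inference ---------------------------------------------------------

    def predict_raw(
        self,
        image: np.ndarray,
        score_threshold: float = 0.3,
        max_detections: int = 60,
    ) -> list[tuple[Box, str, float, Heatmap]]:
        """Raw per-image detections: (box, category, score, heatmap).

        Box-level suppression is *not* applied here; feed the result to
        :func:`pointline.postprocess.detections_to_predictions`.
        """
        img = image.astype(np.float32) / 255.0 - 0.5
        x = nn.Tensor(np.ascontiguousarray(img.transpose(2, 0, 1))[None])
        h, w = image.shape[:2]
        pyramid = self.backbone(x)
        obj, reg, anchors = self._rpn_forward(pyramid)
        props = self._proposals(obj.data, reg.data, anchors, (h, w))
        if len(props) == 0:
            return []
        cls_logits, reg_out = self._box_head(pyramid, props)
        z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        boxes = _decode(props, reg_out.data)
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        cand: list[tuple[float, int, int]] = []  # (score, roi, class_id)
        for ci in range(1, self.cfg.num_classes):
            for ri in range(len(props)):
                s = float(p[ri, ci])
                if s >= score_threshold:
                    cand.append((s, ri, ci))
        cand.sort(key=lambda t: -t[0])
        cand = cand[:max_detections]
        if not cand:
            return []
        final_boxes = np.array([boxes[ri] for _, ri, _ in cand])
        ok = (final_boxes[:, 2] - final_boxes[:, 0] > 2) & (
            final_boxes[:, 3] - final_boxes[:, 1] > 2
        )
        cand = [c for c, k in zip(cand, ok) if k]
        if not cand:
            return []
        final_boxes = final_boxes[ok]
        logits = self._kp_head(pyramid, final_boxes)
        heat = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
        out = []
        for (s, _ri, ci), b, g in zip(cand, final_boxes, heat):
            box = Box(*b)
            out.append((box, CATEGORIES[ci - 1], s, Heatmap(g, box)))
        return out


def build_model(cfg: ModelConfig) -> PointLineNet:
    """Construct a Point-Line Net for the given configuration."""
    return PointLineNet(cfg)


def keypoint_loss(pred_logits, target) -> float:
    """Mean per-cell binary cross-entropy of a heatmap prediction.

    Convenience wrapper accepting plain arrays (or :class:`Heatmap` targets);
    the differentiable path used in training is ``nn.sigmoid_bce_loss``.
    """
    t = target.grid if isinstance(target, Heatmap) else np.asarray(target, dtype=float)
    z = np.asarray(
        pred_logits.grid if isinstance(pred_logits, Heatmap) else pred_logits, dtype=float
    )
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {t.shape}")
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def augment(
    image: np.ndarray,
    ann: AnnotatedImage,
    flip_prob: float = 0.5,
    color_jitter: bool = True,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, AnnotatedImage]:
    """Random horizontal flip (coordinates included) and colour jitter."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    out_img = image
    out_anns = ann.annotations
    if rng.random() < flip_prob:
        out_img = out_img[:, ::-1].copy()
        flipped = []
        for a in out_anns:
            pts = a.points.copy()
            pts[:, 0] = ann.width - 1 - pts[:, 0]
            flipped.append(replace(a, points=pts))
        out_anns = flipped
    if color_jitter:
        gains = rng.uniform(0.85, 1.15, size=3)
        shift = rng.uniform(-12, 12)
        out_img = np.clip(out_img.astype(float) * gains + shift, 0, 255).astype(np.uint8)
    return out_img, AnnotatedImage(ann.image_path, ann.width, ann.height, list(out_anns))


# ------------------------------------------------------------------ training


def _flip_sample(sample: TrainingSample, width: int) -> TrainingSample:
    boxes = sample.boxes.copy()
    if boxes.size:
        x1 = width - 1 - boxes[:, 2]
        x2 = width - 1 - boxes[:, 0]
        boxes[:, 0], boxes[:, 2] = x1, x2
    kps = []
    for k in sample.keypoints:
        k = k.copy()
        k[:, 0] = width - 1 - k[:, 0]
        kps.append(k)
    return TrainingSample(sample.image[:, ::-1].copy(), boxes, sample.labels.copy(), kps)


def train(
    model: PointLineNet,
    train_samples: Sequence[TrainingSample],
    cfg: TrainConfig,
    val_samples: Sequence[TrainingSample] = (),
    log_path: Optional[str | Path] = None,
    eval_every: int = 1,
) -> dict:
    """SGD training loop with StepLR; retains the best weights by val mAP50.

    Returns a history dict with per-epoch learning rate, mean box loss (RPN +
    detection head), mean keypoint loss, and validation mAP50 when computed;
    ``best_state`` holds the weights of the best validation epoch (or the last
    epoch when no validation set is given).
    """
    if len(train_samples) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), cfg.base_lr, cfg.momentum, cfg.weight_decay)
    history: dict = {"epoch": [], "lr": [], "box_loss": [], "kp_loss": [], "val_map50": []}
    best_map, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        opt.lr = learning_rate_at(epoch, cfg)
        order = rng.permutation(len(train_samples))
        box_losses, kp_losses = [], []
        for i in order:
            sample = train_samples[i]
            if rng.random() < cfg.flip_prob:
                sample = _flip_sample(sample, sample.image.shape[1])
            if cfg.color_jitter:
                gains = rng.uniform(0.85, 1.15, size=3)
                sample = TrainingSample(
                    np.clip(sample.image.astype(float) * gains, 0, 255).astype(np.uint8),
                    sample.boxes, sample.labels, sample.keypoints,
                )
            losses = model.losses(sample, rng)
            if not losses:
                continue
            total = nn.scalar_sum(list(losses.values()))
            opt.zero_grad()
            total.backward()
            opt.step()
            box_losses.append(
                sum(float(losses[k].data) for k in ("rpn_obj", "rpn_box", "cls", "box") if k in losses)
            )
            kp_losses.append(float(losses["kp"].data) if "kp" in losses else 0.0)
        val_map = None
        if val_samples and ((epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1):
            val_map = evaluate_map50(model, val_samples)
            if val_map >= best_map:
                best_map = val_map
                best_state = model.state_dict()
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["box_loss"].append(float(np.mean(box_losses)) if box_losses else float("nan"))
        history["kp_loss"].append(float(np.mean(kp_losses)) if kp_losses else float("nan"))
        history["val_map50"].append(val_map)
    if best_state is None:
        best_state = model.state_dict()
        best_map = evaluate_map50(model, val_samples) if val_samples else float("nan")
    else:
        model.load_state_dict(best_state)
    history["best_val_map50"] = best_map
    history["best_state"] = best_state
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "box_loss", "kp_loss", "val_map50"])
            for row in zip(
                history["epoch"], history["lr"], history["box_loss"],
                history["kp_loss"], history["val_map50"],
            ):
                writer.writerow(row)
    return history


def evaluate_map50(model: PointLineNet, samples: Sequence[TrainingSample]) -> float:
    """mAP50 of the model on prepared samples (soft-diou suppression)."""
    from .detmetrics import evaluate_detections
    from .postprocess import NMSConfig, detections_to_predictions

    dets_by, gts_by = {}, {}
    for i, s in enumerate(samples):
        raw = model.predict_raw(s.image)
        dets_by[i] = detections_to_predictions(raw, NMSConfig())
        gts_by[i] = [
            (Box(*b), CATEGORIES[l - 1]) for b, l in zip(s.boxes, s.labels)
        ]
    report = evaluate_detections(dets_by, gts_by, iou_thresholds=(0.5,))
    return report.map_per_threshold[0.5]


def save_checkpoint(path: str | Path, model: PointLineNet, history: Optional[dict] = None) -> None:
    """Persist weights + config (npz)."""
    import json

    meta = {
        "model_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.cfg).items()
        },
    }
    if history is not None:
        meta["history"] = {
            k: v for k, v in history.items() if k != "best_state"
        }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.state_dict(),
    )


def load_checkpoint(path: str | Path) -> tuple[PointLineNet, dict]:
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    mc = meta["model_config"]
    cfg = ModelConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in mc.items()
        }
    )
    model = PointLineNet(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
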