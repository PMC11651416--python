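"""Synthetic maize-like field scenes with dotted-line ground truth.

Real field imagery of maize shows near-vertical stalks with arced leaves
attached to them, photographed against cluttered soil/vegetation backgrounds,
with occlusion between neighbouring plants growing worse late in the season.
This generator emulates that *structure* — not its photometry — so the whole
detection/evaluation pipeline can be exercised without any external database:

* each plant is one jittered near-vertical stalk polyline plus a handful of
  leaves, each leaf a quadratic Bezier arc rooted on the stalk;
* curves are drawn as thick anti-aliased strokes (supersampled 2x) in
  green-hue palettes over either a plain soil background or procedural clutter;
* every drawn curve has a matching :class:`PolylineAnnotation` whose points lie
  on the stroke centerline;
* growth-stage presets (``early`` / ``middle`` / ``late``) control plant count,
  leaf count and lateral spread, so the ``late`` preset produces heavy
  inter-instance overlap.

All randomness flows from ``SceneConfig.seed`` through per-scene substreams,
so identical configs give pixel-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .annotations import AnnotatedImage, PolylineAnnotation, write_labelme

__all__ = ["SceneConfig", "generate_scene", "generate_dataset"]

_STAGE_PRESETS = {
    # n_plants, leaves_per_plant range, lateral leaf spread fraction
    "early": dict(n_plants=2, leaves_per_plant=(2, 3), spread=0.55),
    "middle": dict(n_plants=3, leaves_per_plant=(3, 5), spread=0.75),
    "late": dict(n_plants=5, leaves_per_plant=(5, 7), spread=1.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic field scene."""

    image_size: tuple[int, int] = (256, 256)
    n_plants: int = 2
    leaves_per_plant: tuple[int, int] = (2, 3)
    stage: str = "early"
    occlusion_level: float = 0.3
    background: str = "clutter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not 0.0 <= self.occlusion_level <= 1.0:
            raise ValueError("occlusion_level must be in [0, 1]")
        if self.stage not in _STAGE_PRESETS:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.background not in ("plain", "clutter"):
            raise ValueError(f"unknown background {self.background!r}")
        lo, hi = self.leaves_per_plant
        if lo < 1 or hi < lo:
            raise ValueError("leaves_per_plant must be a valid (lo, hi) range")

    @staticmethod
    def for_stage(stage: str, seed: int = 0, image_size=(256, 256)) -> "SceneConfig":
        """Preset configuration for a growth stage (plant/leaf counts, overlap)."""
        p = _STAGE_PRESETS[stage]
        return SceneConfig(
            image_size=image_size,
            n_plants=p["n_plants"],
            leaves_per_plant=p["leaves_per_plant"],
            stage=stage,
            occlusion_level={"early": 0.2, "middle": 0.45, "late": 0.8}[stage],
            seed=seed,
        )


def _bezier(p0, p1, p2, n: int = 20) -> np.ndarray:
    """Quadratic Bezier sampled at ``n`` points (inclusive of both ends)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _draw_polyline(draw: ImageDraw.ImageDraw, pts: np.ndarray, color, width: int):
    xy = [tuple(p) for p in pts]
    draw.line(xy, fill=color, width=width, joint="curve")


def _background(rng: np.random.Generator, w: int, h: int, kind: str) -> np.ndarray:
    base = np.array([118, 92, 61], dtype=float)  # dry-soil brown
    img = np.tile(base, (h, w, 1))
    img += rng.normal(0.0, 6.0, size=(h, w, 3))
    if kind == "clutter":
        # low-frequency mottling + a few distractor blobs/straw streaks
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(3):
            fx, fy = rng.uniform(0.01, 0.05, size=2)
            ph = rng.uniform(0, 2 * np.pi)
            img += (
                rng.uniform(4, 12)
                * np.sin(2 * np.pi * (fx * xx + fy * yy) + ph)[..., None]
            )
        n_blobs = rng.integers(6, 14)
        for _ in range(n_blobs):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(2, 9)
            col = rng.uniform([60, 70, 40], [160, 150, 110])
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r * r
            img[mask] = 0.6 * img[mask] + 0.4 * col
    return np.clip(img, 0, 255)


def _stalk_polyline(rng, w, h, base_x) -> np.ndarray:
    """5-point jittered near-vertical polyline from near the bottom upward."""
    y0 = rng.uniform(0.88, 0.97) * h
    y1 = rng.uniform(0.12, 0.25) * h
    ys = np.linspace(y0, y1, 5)
    xs = base_x + np.cumsum(rng.normal(0.0, 0.012 * w, size=5))
    xs = np.clip(xs, 2, w - 3)
    ys = np.clip(ys, 2, h - 3)
    return np.stack([xs, ys], axis=1)


def _leaf_arc(rng, stalk: np.ndarray, w, h, spread: float) -> np.ndarray:
    """Quadratic Bezier leaf rooted on the stalk, arcing out and drooping."""
    t = rng.uniform(0.25, 0.95)
    seg = min(int(t * (len(stalk) - 1)), len(stalk) - 2)
    frac = t * (len(stalk) - 1) - seg
    root = stalk[seg] + frac * (stalk[seg + 1] - stalk[seg])
    side = rng.choice([-1.0, 1.0])
    length = rng.uniform(0.18, 0.38) * w * spread
    rise = rng.uniform(0.10, 0.30) * h
    droop = rng.uniform(0.05, 0.30) * h
    ctrl = root + np.array([side * 0.5 * length, -rise])
    tip = root + np.array([side * length, -rise + droop])
    pts = _bezier(root, ctrl, tip, n=20)
    pts[:, 0] = np.clip(pts[:, 0], 1, w - 2)
    pts[:, 1] = np.clip(pts[:, 1], 1, h - 2)
    return pts


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, AnnotatedImage]:
    """Render one scene; returns (HxWx3 uint8 image, matching annotations)."""
    w, h = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    img = _background(rng, w, h, cfg.background)

    ss = 2  # supersampling factor for anti-aliased strokes
    canvas = Image.fromarray(np.zeros((h * ss, w * ss, 4), dtype=np.uint8), "RGBA")
    draw = ImageDraw.Draw(canvas)

    spread = _STAGE_PRESETS[cfg.stage]["spread"]
    # late stage packs plants closer together -> more inter-plant occlusion
    margin = 0.18 - 0.10 * cfg.occlusion_level
    xs = np.linspace(margin * w, (1 - margin) * w, cfg.n_plants)
    xs = xs + rng.uniform(-0.03, 0.03, size=cfg.n_plants) * w

    annotations: list[PolylineAnnotation] = []
    instance = 0
    lo, hi = cfg.leaves_per_plant
    for base_x in xs:
        stalk = _stalk_polyline(rng, w, h, base_x)
        g = rng.uniform(-12, 12)
        stalk_color = (int(92 + g), int(128 + g), int(58 + g), 255)
        _draw_polyline(draw, stalk * ss, stalk_color, width=4 * ss)
        annotations.append(PolylineAnnotation("stalk", instance, stalk.copy()))
        instance += 1
        n_leaves = int(rng.integers(lo, hi + 1))
        for _ in range(n_leaves):
            leaf = _leaf_arc(rng, stalk, w, h, spread)
            g = rng.uniform(-20, 20)
            leaf_color = (int(66 + g), int(142 + g), int(52 + g), 255)
            _draw_polyline(draw, leaf * ss, leaf_color, width=3 * ss)
            annotations.append(PolylineAnnotation("leaf", instance, leaf.copy()))
            instance += 1

    strokes = np.asarray(
        canvas.resize((w, h), Image.Resampling.BILINEAR), dtype=float
    )
    alpha = strokes[..., 3:4] / 255.0
    img = img * (1 - alpha) + strokes[..., :3] * alpha
    out = np.clip(img, 0, 255).astype(np.uint8)
    ann_img = AnnotatedImage(
        image_path=f"scene_{cfg.seed:06d}.png", width=w, height=h,
        annotations=annotations,
    )
    return out, ann_img


def generate_dataset(
    n_scenes: int, cfg: SceneConfig, out_dir: str | Path
) -> list[tuple[Path, Path]]:
    """Write ``n_scenes`` PNG + Labelme JSON pairs plus a seed manifest.

    Per-scene seeds are drawn deterministically from ``cfg.seed`` so the whole
    dataset is reproducible from one integer.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=n_scenes)
    pairs: list[tuple[Path, Path]] = []
    manifest = []
    for i, s in enumerate(scene_seeds):
        scene_cfg = replace(cfg, seed=int(s))
        image, ann = generate_scene(scene_cfg)
        stem = f"scene_{i:04d}"
        ann.image_path = f"{stem}.png"
        img_path = out_dir / f"{stem}.png"
        json_path = out_dir / f"{stem}.json"
        Image.fromarray(image).save(img_path)
        write_labelme(ann, json_path)
        manifest.append({"scene": stem, "seed": int(s), "stage": cfg.stage})
        pairs.append((img_path, json_path))
    with open(out_dir / "scenes.json", "w") as fh:
        json.dump({"master_seed": cfg.seed, "scenes": manifest}, fh, indent=1)
    return pairs
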