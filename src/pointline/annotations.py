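"""Dotted-line annotation I/O and preprocessing.

The annotation dialect is the Labelme JSON flavour used for field-maize
trajectory labelling: each image carries a list of shapes, each shape being a
category (``leaf`` or ``stalk``) plus an ordered list of 2-D points tracing the
leaf midrib or stalk axis.  No boxes or masks are stored; detection boxes are
*derived* from the point extrema plus a fixed padding offset.

Preprocessing pipeline (in the order a dataset goes through it):

1. ``scale_annotated_image`` — downsample image size and point coordinates by a
   common factor (the raw 6016x4016 frames are worked at 1/4 scale, 1504x1004);
2. ``densify_polyline`` — piecewise-linear arc-length interpolation so sparse
   hand-placed points become a dense trajectory;
3. ``subsample_equal_interval`` — retain a fixed fraction (default 30%) of the
   densified points at equally spaced indices as ground-truth keypoints;
4. ``derive_bbox`` — min/max corner box padded by an offset (default 20 px in
   working coordinates) and clipped to the image;
5. ``split_dataset`` — seeded 7:2:1 train/val/test partition;
6. ``export_detection_dataset`` — COCO-style manifest with boxes and per
   instance keypoint arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import Box

__all__ = [
    "CATEGORIES",
    "PolylineAnnotation",
    "AnnotatedImage",
    "SplitSpec",
    "read_labelme",
    "write_labelme",
    "scale_annotated_image",
    "derive_bbox",
    "densify_polyline",
    "subsample_equal_interval",
    "split_dataset",
    "export_detection_dataset",
    "read_manifest",
]

CATEGORIES = ("leaf", "stalk")
CATEGORY_IDS = {"leaf": 1, "stalk": 2}


@dataclass
class PolylineAnnotation:
    """One labelled trajectory: category plus ordered on-trajectory points."""

    category: str
    instance_id: int
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.shape[0] < 1:
            raise ValueError("annotation must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("annotation points must be finite")


@dataclass
class AnnotatedImage:
    image_path: str
    width: int
    height: int
    annotations: list[PolylineAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions plus the shuffle seed."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three non-negative fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")


def read_labelme(path: str | Path) -> AnnotatedImage:
    """Read one Labelme-dialect JSON file into an :class:`AnnotatedImage`.

    Shape labels are matched case-insensitively against ``leaf``/``stalk``;
    anything else raises a ``ValueError`` naming the offending label.
    """
    path = Path(path)
    with open(path) as fh:  # missing file -> FileNotFoundError
        data = json.load(fh)  # malformed -> json.JSONDecodeError
    width = int(data["imageWidth"])
    height = int(data["imageHeight"])
    anns: list[PolylineAnnotation] = []
    for i, shape in enumerate(data.get("shapes", [])):
        label = str(shape["label"]).strip().lower()
        if label not in CATEGORIES:
            raise ValueError(
                f"unsupported label {shape['label']!r} in {path.name}; "
                f"expected one of {CATEGORIES}"
            )
        pts = np.asarray(shape["points"], dtype=float)
        anns.append(PolylineAnnotation(label, instance_id=i, points=pts))
    image_path = str(data.get("imagePath", path.with_suffix(".png").name))
    return AnnotatedImage(image_path, width, height, anns)


def write_labelme(img: AnnotatedImage, path: str | Path) -> None:
    """Write an :class:`AnnotatedImage` as Labelme-dialect JSON."""
    data = {
        "version": "5.0.0",
        "flags": {},
        "imagePath": img.image_path,
        "imageData": None,
        "imageWidth": img.width,
        "imageHeight": img.height,
        "shapes": [
            {
                "label": ann.category,
                "points": ann.points.tolist(),
                "group_id": ann.instance_id,
                "shape_type": "linestrip",
                "flags": {},
            }
            for ann in img.annotations
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def scale_annotated_image(img: AnnotatedImage, factor: float) -> AnnotatedImage:
    """Downscale image dimensions and every annotation point by ``factor``."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    new_w = int(round(img.width / factor))
    new_h = int(round(img.height / factor))
    anns = []
    for ann in img.annotations:
        pts = ann.points / factor
        pts[:, 0] = np.clip(pts[:, 0], 0.0, max(new_w - 1, 0))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, max(new_h - 1, 0))
        anns.append(replace(ann, points=pts))
    return AnnotatedImage(img.image_path, new_w, new_h, anns)


def derive_bbox(
    ann: PolylineAnnotation, offset: float, image_size: tuple[int, int]
) -> Box:
    """Ground-truth box: point extrema padded by ``offset``, clipped to the image.

    The min coordinates give the upper-left corner, the max coordinates the
    lower-right, each pushed outward by ``offset`` pixels so the full organ
    (not just its centerline) is covered.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if ann.points.shape[0] == 0:
        raise ValueError("cannot derive a box from an empty point list")
    w, h = image_size
    x1, y1 = ann.points.min(axis=0)
    x2, y2 = ann.points.max(axis=0)
    box = Box(x1 - offset, y1 - offset, x2 + offset, y2 + offset).clipped(w, h)
    if box.area <= 0:
        raise ValueError("derived box is degenerate after clipping")
    return box


def densify_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Piecewise-linear arc-length interpolation of a polyline.

    Every output point lies exactly on the input polyline, consecutive output
    points are at most ``spacing`` apart along each segment, and the original
    vertices (in particular both endpoints) are retained in order.  Zero-length
    segments are collapsed.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] <= 1:
        return pts.copy()
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        if length == 0.0:
            continue
        n = max(1, int(math.ceil(length / spacing)))
        for i in range(1, n):
            out.append(a + (i / n) * seg)
        out.append(b)  # exact vertex, no interpolation round-off
    return np.asarray(out)


def subsample_equal_interval(points: np.ndarray, ratio: float) -> np.ndarray:
    """Keep ``max(2, round(n * ratio))`` points at equally spaced indices.

    The first and last points are always retained (a single-point input is
    returned unchanged), so the trajectory's extent survives subsampling.  The
    output is a subsequence of the input.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n <= 1:
        return pts.copy()
    k = min(n, max(2, int(round(n * ratio))))
    idx = np.round(np.linspace(0, n - 1, k)).astype(int)
    return pts[idx]


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    sizes = [int(math.floor(q)) for q in quotas]
    short = n - sum(sizes)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in remainders[:short]:
        sizes[i] += 1
    return sizes


def split_dataset(items: Sequence, spec: SplitSpec) -> tuple[list, list, list]:
    """Seeded shuffle followed by largest-remainder apportionment into 3 splits."""
    if len(items) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(items))
    sizes = _largest_remainder(len(items), spec.ratios)
    shuffled = [items[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def export_detection_dataset(
    images: Sequence[AnnotatedImage],
    out_path: str | Path,
    offset: float = 20.0,
    ratio: float = 0.3,
    spacing: float = 5.0,
) -> Path:
    """Write a COCO-style detection manifest with derived boxes and keypoints.

    Each annotation record carries ``bbox`` as ``[x, y, w, h]`` and
    ``keypoints`` as a flat ``[x0, y0, v0, x1, y1, v1, ...]`` array (visibility
    always 2), where the keypoints are the densified-then-subsampled trajectory
    points.  Coordinates round-trip exactly through :func:`read_manifest`.
    """
    if len(images) == 0:
        raise ValueError("no images to export")
    out_path = Path(out_path)
    if out_path.suffix != ".json":
        out_path = out_path / "manifest.json"
    out_path.parent.mkdir(parents=True, exist_ok=True)

    records: dict = {
        "images": [],
        "categories": [
            {"id": cid, "name": name} for name, cid in CATEGORY_IDS.items()
        ],
        "annotations": [],
        "meta": {"offset": offset, "ratio": ratio, "spacing": spacing},
    }
    ann_id = 1
    for img_id, img in enumerate(images, start=1):
        records["images"].append(
            {
                "id": img_id,
                "file_name": img.image_path,
                "width": img.width,
                "height": img.height,
            }
        )
        for ann in img.annotations:
            box = derive_bbox(ann, offset, (img.width, img.height))
            dense = densify_polyline(ann.points, spacing)
            kps = subsample_equal_interval(dense, ratio)
            flat = []
            for x, y in kps:
                flat.extend([float(x), float(y), 2])
            records["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": CATEGORY_IDS[ann.category],
                    "bbox": box.as_xywh(),
                    "area": box.area,
                    "keypoints": flat,
                    "num_keypoints": int(kps.shape[0]),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    with open(out_path, "w") as fh:
        json.dump(records, fh)
    return out_path


def read_manifest(path: str | Path) -> dict:
    """Load an exported manifest; inverse of :func:`export_detection_dataset`."""
    with open(path) as fh:
        return json.load(fh)
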