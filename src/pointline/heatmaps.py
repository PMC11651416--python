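"""Single-heatmap keypoint targets.

Instead of one heatmap per anatomically fixed keypoint (the human-pose
convention), every detected instance gets exactly one probability grid in
which *all* of its trajectory points appear as peaks.  Training targets are
rendered here; peak extraction back to image coordinates lives in
:mod:`pointline.postprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Box

__all__ = ["Heatmap", "render_target_heatmap", "grid_to_image", "image_to_grid"]


@dataclass
class Heatmap:
    """A size x size grid of values in [0, 1], registered to a detection box."""

    grid: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("heatmap grid must be 2-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("heatmap values must be finite")

    @property
    def size(self) -> tuple[int, int]:
        return self.grid.shape


def image_to_grid(xy: np.ndarray, box: Box, size: int) -> np.ndarray:
    """Map image coordinates to continuous (col, row) grid coordinates.

    Cell centers sit at half-integer fractions of the box, i.e. cell ``c``
    spans ``[c, c+1) * box.width / size`` with its center at ``c + 0.5``.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    gx = (xy[:, 0] - box.x1) / max(box.width, 1e-12) * size - 0.5
    gy = (xy[:, 1] - box.y1) / max(box.height, 1e-12) * size - 0.5
    return np.stack([gx, gy], axis=1)


def grid_to_image(cells: np.ndarray, box: Box, size: int) -> np.ndarray:
    """Map (col, row) grid coordinates (cell centers) back to image pixels."""
    cells = np.asarray(cells, dtype=float).reshape(-1, 2)
    x = box.x1 + (cells[:, 0] + 0.5) / size * box.width
    y = box.y1 + (cells[:, 1] + 0.5) / size * box.height
    return np.stack([x, y], axis=1)


def render_target_heatmap(
    keypoints: np.ndarray,
    box: Box,
    size: int = 56,
    sigma_hm: float = 2.0,
) -> Heatmap:
    """Render the training target: max-combined unit-peak Gaussians.

    Each keypoint is snapped to its nearest grid cell (keypoints outside the
    box clip to the boundary cell) and contributes an unnormalised Gaussian of
    width ``sigma_hm`` grid cells with value exactly 1 at that cell.  Where
    Gaussians overlap, the cell takes the maximum, so every keypoint remains a
    local maximum of value 1 when peaks are separated.  An empty keypoint list
    yields an all-zero heatmap.
    """
    if size < 2:
        raise ValueError("heatmap size must be >= 2")
    if sigma_hm <= 0:
        raise ValueError("sigma_hm must be positive")
    grid = np.zeros((size, size), dtype=float)
    kps = np.asarray(keypoints, dtype=float).reshape(-1, 2)
    if kps.shape[0] == 0:
        return Heatmap(grid, box)
    g = image_to_grid(kps, box, size)
    cols = np.clip(np.round(g[:, 0]), 0, size - 1).astype(int)
    rows = np.clip(np.round(g[:, 1]), 0, size - 1).astype(int)
    rr, cc = np.mgrid[0:size, 0:size]
    for r, c in zip(rows, cols):
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        np.maximum(grid, np.exp(-d2 / (2.0 * sigma_hm**2)), out=grid)
    return Heatmap(grid, box)
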