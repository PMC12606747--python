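"""Training-target construction at the output stride.

Three supervision signals are encoded per image:

- a center heatmap with a penalty-reduced Gaussian peak (value exactly 1
  at the quantized center cell of every instance);
- per-keypoint heatmaps with Gaussians at labeled keypoints (auxiliary,
  train-time only);
- offset targets: at each instance's center cell, the displacement from
  the center to every labeled keypoint, expressed in output-stride pixel
  units, together with a validity mask.

Gaussian spread follows the CornerNet-style radius: the largest radius
such that a corner displaced by it still yields at least `iou_floor` IoU
with the ground-truth box, with sigma = radius / 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .schema import PoseInstance, SkeletonSchema

__all__ = ["TrainingTargets", "gaussian_radius", "encode_targets"]

log = logging.getLogger(__name__)


@dataclass
class TrainingTargets:
    center_heatmap: np.ndarray    # (1, h, w) in [0, 1]
    keypoint_heatmaps: np.ndarray  # (K, h, w) in [0, 1]
    offset_targets: np.ndarray    # (2K, h, w), output-stride pixel units
    offset_mask: np.ndarray       # (K, h, w) binary
    n_pos_centers: int
    n_pos_keypoints: int
    n_center_collisions: int = 0
    stride: int = 4


def gaussian_radius(bbox_h: float, bbox_w: float, iou_floor: float = 0.3) -> float:
    """Largest corner displacement keeping IoU >= iou_floor (CornerNet rule).

    Three displacement regimes (both corners inward, both outward, one of
    each) give three quadratics; the result is the minimum of their
    positive roots, clamped to >= 1 output pixel.
    """
    h, w = float(bbox_h), float(bbox_w)

    a1 = 1.0
    b1 = h + w
    c1 = w * h * (1 - iou_floor) / (1 + iou_floor)
    r1 = (-b1 + np.sqrt(b1**2 + 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (h + w)
    c2 = (1 - iou_floor) * w * h
    r2 = (-b2 + np.sqrt(b2**2 + 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * iou_floor
    b3 = -2 * iou_floor * (h + w)
    c3 = (iou_floor - 1) * w * h
    r3 = (b3 + np.sqrt(b3**2 - 4 * a3 * c3)) / (2 * a3)
    return max(1.0, min(r1, r2, r3))


def _draw_gaussian(heatmap: np.ndarray, cx: int, cy: int, sigma: float) -> None:
    """Max-compose an unnormalized Gaussian peak into a 2-D heatmap."""
    h, w = heatmap.shape
    r = max(1, int(np.ceil(3 * sigma)))
    x0, x1 = max(0, cx - r), min(w - 1, cx + r)
    y0, y1 = max(0, cy - r), min(h - 1, cy + r)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    patch = heatmap[y0 : y1 + 1, x0 : x1 + 1]
    np.maximum(patch, g, out=patch)


def encode_targets(
    instances: list,
    schema: SkeletonSchema,
    image_size: tuple,
    stride: int = 4,
    iou_floor: float = 0.3,
) -> TrainingTargets:
    """Encode per-image supervision grids at 1/stride resolution.

    Centers are quantized by floor to their output cell; when two
    instances land on the same cell, the later one wins the offset slots
    (collisions are counted and reported). Instances with no labeled
    keypoint are skipped with a warning.
    """
    ih, iw = image_size
    if ih % stride or iw % stride:
        raise ValueError(f"stride {stride} must divide image size {image_size}")
    h, w = ih // stride, iw // stride
    k = schema.n_keypoints
    center_hm = np.zeros((1, h, w))
    kp_hm = np.zeros((k, h, w))
    off = np.zeros((2 * k, h, w))
    mask = np.zeros((k, h, w))
    n_pos = 0
    n_pos_kp = 0
    collisions = 0
    taken = np.zeros((h, w), dtype=bool)

    for inst in instances:
        vis = inst.visible
        if not vis.any():
            log.warning("instance %s has no labeled keypoint; skipped", inst.instance_id)
            continue
        pts = inst.keypoints[vis, :2]
        bw = max(pts[:, 0].max() - pts[:, 0].min(), 1.0) / stride
        bh = max(pts[:, 1].max() - pts[:, 1].min(), 1.0) / stride
        sigma = gaussian_radius(bh, bw, iou_floor) / 3.0
        if inst.center is None:
            raise ValueError("instance has no center; set PoseInstance.center first")
        cx_f, cy_f = inst.center[0] / stride, inst.center[1] / stride
        cx, cy = int(np.floor(cx_f)), int(np.floor(cy_f))
        cx, cy = np.clip(cx, 0, w - 1), np.clip(cy, 0, h - 1)
        _draw_gaussian(center_hm[0], cx, cy, sigma)
        center_hm[0, cy, cx] = 1.0
        if taken[cy, cx]:
            collisions += 1
            off[:, cy, cx] = 0.0
            mask[:, cy, cx] = 0.0  # last instance wins the cell outright
        taken[cy, cx] = True
        n_pos += 1
        for n in range(k):
            x, y, v = inst.keypoints[n]
            if v <= 0:
                continue
            off[2 * n, cy, cx] = x / stride - cx
            off[2 * n + 1, cy, cx] = y / stride - cy
            mask[n, cy, cx] = 1.0
            n_pos_kp += 1
            kx, ky = int(np.floor(x / stride)), int(np.floor(y / stride))
            if 0 <= kx < w and 0 <= ky < h:
                _draw_gaussian(kp_hm[n], kx, ky, sigma)
                kp_hm[n, ky, kx] = 1.0

    return TrainingTargets(
        center_heatmap=center_hm,
        keypoint_heatmaps=kp_hm,
        offset_targets=off,
        offset_mask=mask,
        n_pos_centers=n_pos,
        n_pos_keypoints=int(mask.sum()),
        n_center_collisions=collisions,
        stride=stride,
    )
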