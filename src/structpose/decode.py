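"""Decode network outputs into scored multi-instance poses.

Centers are 3x3 local maxima of the center heatmap above a score
threshold; each surviving center anchors one pose whose keypoints are
the center location plus the summed two-hop offsets, all read at the
center cell (the part-point shift is already baked into the sampled
features, so the regressed fields live on the center's cell). Decoding
never touches the keypoint-heatmap branch, so removing that branch at
inference cannot change results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .schema import SkeletonSchema, flip_permutation

__all__ = ["DecodedPose", "find_centers", "compose_pose", "decode", "flip_fuse"]


@dataclass
class DecodedPose:
    keypoints: np.ndarray  # (K, 2) input-pixel coordinates
    score: float
    center: tuple          # input-pixel coordinates
    image_id: int = 0

    def to_coco(self, category_id: int = 1) -> dict:
        kps = np.column_stack([self.keypoints, np.full(len(self.keypoints), 2.0)])
        return {
            "image_id": int(self.image_id),
            "category_id": category_id,
            "keypoints": [round(float(v), 2) for v in kps.ravel()],
            "score": float(self.score),
        }


def find_centers(center_heatmap: np.ndarray, max_det: int = 30,
                 score_thresh: float = 0.05) -> list:
    """3x3 local maxima above threshold, best-first.

    Ties are broken deterministically by (row, col). Returns a list of
    ((row, col), score).
    """
    hm = np.asarray(center_heatmap)
    if hm.ndim == 3:
        hm = hm[0]
    local_max = ndimage.maximum_filter(hm, size=3, mode="constant") == hm
    rows, cols = np.nonzero(local_max & (hm >= score_thresh))
    scores = hm[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    order = order[:max_det]
    return [((int(rows[i]), int(cols[i])), float(scores[i])) for i in order]


def compose_pose(center_cell: tuple, score: float, off1_field: np.ndarray,
                 off2_field: np.ndarray, schema: SkeletonSchema,
                 stride: int = 4, off2_at_part: bool = False) -> DecodedPose:
    """Keypoints = stride * (center + off1[part] + off2[keypoint]).

    By default both fields are read at the center cell. With
    ``off2_at_part`` the second hop is instead read at the cell nearest
    the first-hop part point (the alternative dataflow reading).
    """
    cy, cx = center_cell
    h, w = off1_field.shape[-2:]
    owner = schema.part_of_keypoint()
    kps = np.zeros((schema.n_keypoints, 2))
    for n in range(schema.n_keypoints):
        p = owner[n]
        o1 = off1_field[2 * p : 2 * p + 2, cy, cx]
        if off2_at_part:
            py = int(np.clip(round(cy + o1[1]), 0, h - 1))
            px = int(np.clip(round(cx + o1[0]), 0, w - 1))
            o2 = off2_field[2 * n : 2 * n + 2, py, px]
        else:
            o2 = off2_field[2 * n : 2 * n + 2, cy, cx]
        kps[n] = stride * np.array([cx + o1[0] + o2[0], cy + o1[1] + o2[1]])
    return DecodedPose(keypoints=kps, score=score, center=(stride * cx, stride * cy))


def decode(outputs: dict, schema: SkeletonSchema, stride: int = 4,
           max_det: int = 30, score_thresh: float = 0.05,
           off2_at_part: bool = False, image_id: int = 0,
           scale_back: float = 1.0) -> list:
    """NetworkOutputs (numpy arrays, no batch dim) -> list of DecodedPose.

    ``scale_back`` multiplies coordinates to undo any inference-time
    resize back to original image pixels.
    """
    centers = find_centers(outputs["center_heatmap"], max_det, score_thresh)
    poses = []
    for cell, score in centers:
        pose = compose_pose(
            cell, score, outputs["off1_field"], outputs["off2_field"],
            schema, stride, off2_at_part,
        )
        if scale_back != 1.0:
            pose.keypoints = pose.keypoints * scale_back
            pose.center = (pose.center[0] * scale_back, pose.center[1] * scale_back)
        pose.image_id = image_id
        poses.append(pose)
    return poses


def flip_fuse(poses: list, poses_flipped: list, flip_perm: np.ndarray,
              image_w: int, match_radius: float = 16.0) -> list:
    """Fuse direct and mirror-pass detections.

    Flipped poses are un-mirrored (x -> W-1-x) and index-permuted, then
    matched to direct poses by center distance; matched pairs average
    coordinates and scores, unmatched poses pass through.
    """
    unflipped = []
    for pose in poses_flipped:
        kps = pose.keypoints[flip_perm].copy()
        kps[:, 0] = image_w - 1 - kps[:, 0]
        unflipped.append(
            DecodedPose(
                keypoints=kps,
                score=pose.score,
                center=(image_w - 1 - pose.center[0], pose.center[1]),
                image_id=pose.image_id,
            )
        )
    used = np.zeros(len(unflipped), dtype=bool)
    fused = []
    for pose in poses:
        best, best_d = -1, match_radius
        for j, cand in enumerate(unflipped):
            if used[j]:
                continue
            d = float(np.hypot(pose.center[0] - cand.center[0], pose.center[1] - cand.center[1]))
            if d < best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            cand = unflipped[best]
            fused.append(
                DecodedPose(
                    keypoints=(pose.keypoints + cand.keypoints) / 2.0,
                    score=(pose.score + cand.score) / 2.0,
                    center=(
                        (pose.center[0] + cand.center[0]) / 2.0,
                        (pose.center[1] + cand.center[1]) / 2.0,
                    ),
                    image_id=pose.image_id,
                )
            )
        else:
            fused.append(pose)
    fused.extend(c for j, c in enumerate(unflipped) if not used[j])
    return fused
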