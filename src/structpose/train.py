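"""Training loop, learning-rate schedules, augmentation and inference.

Optimization follows the usual center-heatmap recipe: Adam with weight
decay 1e-4, initial LR 1.25e-4 annealed to 1e-5 either by cosine
(default) or by x10 step drops at configurable milestone epochs, and
affine augmentation (rotation +-30 deg, scale 0.75-1.5, translation
+-40 px, horizontal flip with p=0.5).

Everything is seeded: (scene seed, train seed) fully determine the loss
trace and metrics log.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .decode import decode
from .evaluation import evaluate
from .losses import (
    LossConfig,
    center_focal_loss,
    gather_predicted_offsets,
    keypoint_focal_loss,
    offset_l1_loss,
    total_loss,
)
from .model import ModelConfig, StructPoseNet, build_model
from .nn import Adam
from .schema import PoseInstance, SkeletonSchema, flip_permutation, instance_center
from .targets import encode_targets

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "cosine_lr",
    "step_lr",
    "augment_sample",
    "train",
    "infer_sample",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentConfig:
    rot_deg: tuple = (-30.0, 30.0)
    scale: tuple = (0.75, 1.5)
    translate_px: tuple = (-40.0, 40.0)
    hflip_p: float = 0.5


@dataclass
class TrainConfig:
    eta0: float = 1.25e-4
    eta_min: float = 1.0e-5
    t_max: int = 140
    batch_size: int = 4
    input_size: tuple = (128, 128)
    seed: int = 0
    schedule: str = "cosine"          # or "step"
    step_milestones: tuple = (90, 120)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    weight_decay: float = 1.0e-4
    stride: int = 4
    loss: LossConfig = field(default_factory=LossConfig)
    eval_every: int = 0               # epochs; 0 = only at the end

    def __post_init__(self):
        if not (0 < self.eta_min < self.eta0):
            raise ValueError("require 0 < eta_min < eta0")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


def cosine_lr(t_cur: int, cfg: TrainConfig) -> float:
    """Cosine annealing from eta0 (t=0) to eta_min (t=t_max)."""
    if t_cur > cfg.t_max:
        log.warning("t_cur %d beyond t_max %d; clamping to eta_min", t_cur, cfg.t_max)
        return cfg.eta_min
    return cfg.eta_min + 0.5 * (cfg.eta0 - cfg.eta_min) * (
        1.0 + math.cos(t_cur / cfg.t_max * math.pi)
    )


def step_lr(t_cur: int, cfg: TrainConfig) -> float:
    """eta0 decayed x10 at each milestone epoch."""
    drops = sum(1 for m in cfg.step_milestones if t_cur >= m)
    return cfg.eta0 * (0.1**drops)


def schedule_lr(t_cur: int, cfg: TrainConfig) -> float:
    return cosine_lr(t_cur, cfg) if cfg.schedule == "cosine" else step_lr(t_cur, cfg)


# ---------------------------------------------------------------------------
# Augmentation


def augment_sample(image: np.ndarray, instances: list, rng: np.random.Generator,
                   schema: SkeletonSchema, aug: AugmentConfig = AugmentConfig()):
    """One random affine (rotate about center, scale, translate) plus an
    optional mirror, applied identically to image and keypoints.

    Keypoints pushed outside the canvas get v=0. Border fill is the
    image mean. Returns (image', instances')."""
    h, w = image.shape[:2]
    theta = math.radians(rng.uniform(*aug.rot_deg))
    s = rng.uniform(*aug.scale)
    tx, ty = rng.uniform(*aug.translate_px, size=2)
    do_flip = rng.uniform() < aug.hflip_p

    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rot = s * np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
    shift = c + np.array([tx, ty]) - rot @ c
    inv = np.linalg.inv(rot)

    # scipy's affine_transform maps output -> input in (row, col) order
    m_rc = inv[::-1, ::-1]
    off_rc = (-inv @ shift)[::-1]
    fill = float(image.mean())
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            image[:, :, ch], m_rc, offset=off_rc, order=1, mode="constant", cval=fill
        )
    perm = flip_permutation(schema)
    new_instances = []
    for inst in instances:
        kps = inst.keypoints.copy()
        xy = (rot @ kps[:, :2].T).T + shift
        kps[:, :2] = xy
        oob = (xy[:, 0] < 0) | (xy[:, 0] > w - 1) | (xy[:, 1] < 0) | (xy[:, 1] > h - 1)
        kps[oob, 2] = 0.0
        if do_flip:
            kps = kps[perm]
            kps[:, 0] = np.where(kps[:, 2] > 0, w - 1 - kps[:, 0], kps[:, 0])
        ni = PoseInstance(keypoints=kps, instance_id=inst.instance_id)
        if ni.visible.any():
            ni.center = instance_center(ni, schema)
            ni.scale_s = ni.compute_scale()
            new_instances.append(ni)
    if do_flip:
        out = out[:, ::-1].copy()
    return out, new_instances


# ---------------------------------------------------------------------------
# Training


def _batch_loss(model: StructPoseNet, images: np.ndarray, target_list,
                loss_cfg: LossConfig):
    x = Tensor(images.transpose(0, 3, 1, 2))
    out = model.forward(x, train=True)
    hm_t = np.stack([t.center_heatmap for t in target_list])
    kp_t = np.stack([t.keypoint_heatmaps for t in target_list])
    n_pos = max(sum(t.n_pos_centers for t in target_list), 1)
    n_pos_kp = max(sum(t.n_pos_keypoints for t in target_list), 1)
    l_hm = center_focal_loss(out["center_heatmap"], hm_t, n_pos, loss_cfg)
    l_hm_hp = keypoint_focal_loss(out["keypoint_heatmaps"], kp_t, n_pos_kp, loss_cfg)
    pred, tgt, mask = gather_predicted_offsets(
        out["off1_field"], out["off2_field"], target_list, model.schema.part_of_keypoint()
    )
    l_hp = offset_l1_loss(pred, tgt, mask, loss_cfg)
    loss = total_loss(l_hm, l_hp, l_hm_hp, loss_cfg)
    return loss, {
        "loss": float(loss.data),
        "loss_hm": float(l_hm.data),
        "loss_hp": float(l_hp.data),
        "loss_hm_hp": float(l_hm_hp.data),
    }


def evaluate_on_samples(model: StructPoseNet, samples, stride=4, max_det=30,
                        score_thresh=0.05):
    preds, gts = {}, {}
    for s in samples:
        out = model.predict(s.image)
        image_id = s.image_id
        preds[image_id] = decode(out, model.schema, stride=stride, max_det=max_det,
                                 score_thresh=score_thresh, image_id=image_id)
        gts[image_id] = [g for g in s.instances if g.visible.any()]
    return evaluate(preds, gts, model.schema, max_det=max_det)


def train(cfg: TrainConfig, samples: list, model_cfg: ModelConfig | None = None,
          model: StructPoseNet | None = None, out_dir=None, log_fn=None):
    """Train on in-memory SceneSamples; returns (model, history).

    history is a list of per-epoch dicts (lr, branch losses, optional
    eval metrics), also written as JSONL when out_dir is given.
    """
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model_cfg = model_cfg or ModelConfig(seed=cfg.seed)
        model = build_model(model_cfg)
    schema = model.schema
    opt = Adam(model.parameters(), lr=cfg.eta0, weight_decay=cfg.weight_decay)
    model.train()
    history = []
    out_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "train_log.jsonl"
        out_path.write_text("")
    n = len(samples)
    for epoch in range(cfg.t_max):
        lr = schedule_lr(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        stats = {"loss": 0.0, "loss_hm": 0.0, "loss_hp": 0.0, "loss_hm_hp": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs, tlists = [], []
            for i in idx:
                s = samples[i]
                img, insts = s.image, s.instances
                if cfg.augment is not None:
                    img, insts = augment_sample(img, insts, rng, schema, cfg.augment)
                if not any(ins.visible.any() for ins in insts):
                    continue
                imgs.append(img)
                tlists.append(
                    encode_targets(insts, schema, img.shape[:2], stride=cfg.stride)
                )
            if not imgs:
                continue
            loss, bstats = _batch_loss(model, np.stack(imgs), tlists, cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in stats:
                stats[k] += bstats[k]
            n_batches += 1
        for k in stats:
            stats[k] /= max(n_batches, 1)
        rec = {"epoch": epoch, "lr": lr, **stats}
        if cfg.eval_every and (epoch + 1) % cfg.eval_every == 0:
            res = evaluate_on_samples(model, samples, stride=cfg.stride)
            rec.update({"ap": res.ap, "ap50": res.ap50, "ar": res.ar})
        history.append(rec)
        if log_fn:
            log_fn(rec)
        if out_path is not None:
            with out_path.open("a") as fh:
                fh.write(json.dumps(rec) + "\n")
    return model, history


# ---------------------------------------------------------------------------
# Inference


def _resize_to_short_side(image: np.ndarray, short_side: int | None):
    h, w = image.shape[:2]
    if short_side is None:
        scale = 1.0
    else:
        scale = short_side / min(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if (nh, nw) != (h, w):
        image = ndimage.zoom(image, (nh / h, nw / w, 1.0), order=1)
    ph, pw = (-image.shape[0]) % 32, (-image.shape[1]) % 32
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="edge")
    return image, scale


def infer_sample(model: StructPoseNet, image: np.ndarray, image_id: int = 0,
                 short_side: int | None = None, flip_test: bool = False,
                 stride: int = 4, max_det: int = 30, score_thresh: float = 0.05):
    """Forward one image (infer mode) and decode; optional flip-test fusion.

    The image is resized so its short side matches ``short_side`` (if
    given), padded to a multiple of 32, and decoded poses are rescaled
    to original pixel coordinates.
    """
    resized, scale = _resize_to_short_side(image, short_side)
    out = model.predict(resized)
    poses = decode(out, model.schema, stride=stride, max_det=max_det,
                   score_thresh=score_thresh, image_id=image_id,
                   scale_back=1.0 / scale)
    if flip_test:
        flipped = resized[:, ::-1].copy()
        out_f = model.predict(flipped)
        poses_f = decode(out_f, model.schema, stride=stride, max_det=max_det,
                         score_thresh=score_thresh, image_id=image_id,
                         scale_back=1.0 / scale)
        perm = flip_permutation(model.schema)
        from .decode import flip_fuse

        poses = flip_fuse(poses, poses_f, perm, image_w=image.shape[1])
    return poses
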