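"""Training objectives: penalty-reduced focal losses and the two-hop L1.

The heatmap losses use the penalty-reduced focal form

    L = -1/N [ sum_{t=1} (1-p)^a log p  +  sum_{t<1} (1-t)^b p^a log(1-p) ]

with a=2, b=4: cells under the Gaussian tail of a true peak (t close
to 1) are penalized less for firing. The leading minus is the standard
sign convention making the loss non-negative.

The offset loss is an L1 penalty on the *summed* two-hop displacement
gathered at ground-truth center cells — the split between first and
second hop is unconstrained, which is what lets the part points float
to wherever they help. By default the sum of absolute errors is
normalized by the number of supervised keypoint coordinates
(``raw_sum=True`` restores the bare sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "center_focal_loss",
    "keypoint_focal_loss",
    "offset_l1_loss",
    "gather_predicted_offsets",
    "total_loss",
]

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 2.0
    beta: float = 4.0
    lambda_hm: float = 1.0
    lambda_hp: float = 1.0
    lambda_hm_hp: float = 1.0
    raw_sum_offsets: bool = False

    def __post_init__(self):
        for name in ("alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _focal(pred, target: np.ndarray, n_pos: int, cfg: LossConfig) -> Tensor:
    pred = _as_tensor(pred).clip(_EPS, 1.0 - _EPS)
    target = np.asarray(target, dtype=float)
    pos = (target >= 1.0).astype(float)
    neg = 1.0 - pos
    if n_pos < 1:
        log.warning("focal loss with n_pos=0; dividing by 1")
        n_pos = 1
    pos_term = ((1.0 - pred) ** cfg.alpha) * pred.log() * pos
    neg_w = (1.0 - target) ** cfg.beta
    neg_term = (pred**cfg.alpha) * (1.0 - pred).log() * (neg_w * neg)
    return -(pos_term.sum() + neg_term.sum()) / float(n_pos)


def center_focal_loss(pred, target, n_pos: int, cfg: LossConfig = LossConfig()) -> Tensor:
    """Penalty-reduced focal loss for the center heatmap (any leading dims)."""
    return _focal(pred, target, n_pos, cfg)


def keypoint_focal_loss(pred, target, n_pos: int, cfg: LossConfig = LossConfig()) -> Tensor:
    """Same functional form as the center loss, over K keypoint channels."""
    return _focal(pred, target, n_pos, cfg)


def gather_predicted_offsets(off1, off2, targets, part_of_kp: np.ndarray):
    """Sum the two hops at ground-truth center cells.

    off1: (B, 2P, h, w); off2: (B, 2K, h, w); `targets` is a list of
    per-image TrainingTargets (length B). Returns (pred, target, mask)
    each of shape (B, 2K, h, w) with pred = off1[part-of-n] + off2[n].
    """
    off1 = _as_tensor(off1)
    off2 = _as_tensor(off2)
    k = len(part_of_kp)
    chan = np.empty(2 * k, dtype=int)
    chan[0::2] = 2 * part_of_kp
    chan[1::2] = 2 * part_of_kp + 1
    pred = off1[:, chan] + off2
    tgt = np.stack([t.offset_targets for t in targets])
    mask = np.stack([np.repeat(t.offset_mask, 2, axis=0) for t in targets])
    return pred, tgt, mask


def offset_l1_loss(pred_off, target_off: np.ndarray, mask: np.ndarray,
                   cfg: LossConfig = LossConfig()) -> Tensor:
    """L1 on the summed center-to-keypoint displacement at labeled entries.

    `mask` marks the two coordinate channels of each supervised keypoint
    at its instance's center cell; entries outside the mask contribute
    nothing. Normalized by keypoint count (= mask.sum() / 2) unless
    ``cfg.raw_sum_offsets``.
    """
    pred_off = _as_tensor(pred_off)
    mask = np.asarray(mask, dtype=float)
    n_kp = mask.sum() / 2.0
    if n_kp < 1:
        log.warning("offset loss with empty mask; returning 0")
        return Tensor(0.0)
    diff = ((pred_off - target_off) * mask).abs().sum()
    if cfg.raw_sum_offsets:
        return diff
    return diff / float(n_kp)


def total_loss(l_hm, l_hp, l_hm_hp, cfg: LossConfig = LossConfig()) -> Tensor:
    """Weighted sum of the three branch losses."""
    parts = {"center_heatmap": l_hm, "offset": l_hp, "keypoint_heatmap": l_hm_hp}
    for name, val in parts.items():
        v = val.data if isinstance(val, Tensor) else np.asarray(val)
        if not np.isfinite(v).all():
            raise FloatingPointError(f"non-finite loss in {name} branch")
    l_hm, l_hp, l_hm_hp = (_as_tensor(v) for v in (l_hm, l_hp, l_hm_hp))
    return l_hm * cfg.lambda_hm + l_hp * cfg.lambda_hp + l_hm_hp * cfg.lambda_hm_hp
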