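"""OKS-based evaluation: AP / AP50 / AP75 / AR in the COCO style.

Object Keypoint Similarity between a predicted and a ground-truth pose:

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

with d_i the Euclidean keypoint error in input pixels, s the object's
scale (sqrt of the padded tight-bbox area of its labeled keypoints), and
k_i a per-keypoint falloff constant from the schema (uniform 0.1 by
default — no per-keypoint constants are published for these species, so
metrics are self-consistent rather than comparable across toolchains).

AP at one OKS threshold is the 101-point-interpolated area under the
score-ranked precision-recall curve over all images; AP averages the
thresholds 0.50:0.05:0.95, and AR is recall at ``max_det`` detections
per image averaged over the same thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decode import DecodedPose
from .schema import PoseInstance, SkeletonSchema

__all__ = ["EvalResult", "oks", "match_and_score", "evaluate", "OKS_THRESHOLDS"]

OKS_THRESHOLDS = np.round(np.arange(0.50, 0.951, 0.05), 2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalResult:
    ap: float
    ap50: float
    ap75: float
    ar: float
    per_threshold: list = field(default_factory=list)

    def summary(self) -> str:
        rows = [
            f"AP   (OKS 0.50:0.95) {self.ap:6.3f}",
            f"AP50                 {self.ap50:6.3f}",
            f"AP75                 {self.ap75:6.3f}",
            f"AR   (OKS 0.50:0.95) {self.ar:6.3f}",
        ]
        return "\n".join(rows)


def oks(pred: DecodedPose, gt: PoseInstance, schema: SkeletonSchema) -> float:
    """Mean Gaussian keypoint similarity over the GT's labeled keypoints."""
    vis = gt.visible
    if not vis.any():
        raise ValueError("OKS undefined for a GT instance with no labeled keypoint")
    s = gt.scale_s if gt.scale_s is not None else gt.compute_scale()
    if s <= 0:
        raise ValueError("OKS requires a positive GT scale")
    ks = schema.oks_sigmas[vis]
    d2 = np.sum((pred.keypoints[vis] - gt.keypoints[vis, :2]) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * s**2 * ks**2))))


def match_and_score(preds: list, gts: list, schema: SkeletonSchema,
                    threshold: float) -> dict:
    """Greedy one-to-one matching at a fixed OKS threshold.

    Predictions are taken best-score-first; each claims the unmatched GT
    with the highest OKS if that OKS clears the threshold. Returns
    per-prediction TP flags (in score order), plus counts.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    usable = [g for g in gts if g.visible.any()]
    matched = np.zeros(len(usable), dtype=bool)
    tp = np.zeros(len(preds), dtype=bool)
    match_of = np.full(len(preds), -1, dtype=int)
    for rank, pi in enumerate(order):
        best_j, best_oks = -1, threshold
        for j, gt in enumerate(usable):
            if matched[j]:
                continue
            val = oks(preds[pi], gt, schema)
            if val >= best_oks:
                best_j, best_oks = j, val
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = True
            match_of[rank] = best_j
    return {
        "tp": tp,                      # in descending-score order
        "scores": np.array([preds[i].score for i in order]),
        "match_of": match_of,
        "n_gt": len(usable),
        "n_fp": int(len(preds) - tp.sum()),
        "n_fn": int(len(usable) - tp.sum()),
    }


def _ap_at_threshold(all_preds: dict, all_gts: dict, schema, thr, max_det):
    scores, tps = [], []
    n_gt = 0
    for image_id, gts in all_gts.items():
        preds = sorted(all_preds.get(image_id, []), key=lambda p: -p.score)[:max_det]
        res = match_and_score(preds, gts, schema, thr)
        scores.append(res["scores"])
        tps.append(res["tp"])
        n_gt += res["n_gt"]
    scores = np.concatenate(scores) if scores else np.empty(0)
    tps = np.concatenate(tps) if tps else np.empty(0, dtype=bool)
    if n_gt == 0:
        raise ValueError("evaluation requires at least one GT instance")
    order = np.argsort(-scores, kind="stable")
    tps = tps[order]
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # 101-point interpolation: precision envelope sampled on the recall grid
    prec_env = precision.copy()
    for i in range(len(prec_env) - 2, -1, -1):
        prec_env[i] = max(prec_env[i], prec_env[i + 1])
    q = np.zeros(len(RECALL_GRID))
    if len(prec_env):
        idx = np.searchsorted(recall, RECALL_GRID, side="left")
        valid = idx < len(prec_env)
        q[valid] = prec_env[idx[valid]]
    ap = float(q.mean())
    rec = float(recall[-1]) if len(recall) else 0.0
    return ap, rec


def evaluate(all_preds, all_gts, schema: SkeletonSchema, max_det: int = 30,
             thresholds=OKS_THRESHOLDS) -> EvalResult:
    """Aggregate AP/AR over images.

    `all_preds` / `all_gts` are dicts image_id -> list (DecodedPose /
    PoseInstance), or flat lists of DecodedPose with image_id set and
    (image_id, instances) handled by the caller.
    """
    if not isinstance(all_gts, dict):
        raise TypeError("all_gts must be a dict image_id -> [PoseInstance]")
    if not isinstance(all_preds, dict):
        grouped: dict = {}
        for p in all_preds:
            grouped.setdefault(p.image_id, []).append(p)
        all_preds = grouped
    per_thr = []
    recalls = []
    for thr in thresholds:
        ap, rec = _ap_at_threshold(all_preds, all_gts, schema, float(thr), max_det)
        per_thr.append(ap)
        recalls.append(rec)
    thr_list = [float(t) for t in thresholds]

    def at(t):
        return per_thr[thr_list.index(t)] if t in thr_list else float("nan")

    return EvalResult(
        ap=float(np.mean(per_thr)),
        ap50=at(0.5),
        ap75=at(0.75),
        ar=float(np.mean(recalls)),
        per_threshold=list(zip(thr_list, per_thr)),
    )
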