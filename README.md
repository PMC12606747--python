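# structpose

Single-stage, structure-aware 2D pose estimation for **multiple
animals per image** — built for the dense, occlusion-heavy recordings
typical of behavioral experiments on small model organisms
(*C. elegans*, zebrafish, *Drosophila*), where 1–15 visually similar,
highly deformable individuals overlap in every frame and two-stage
detect-then-pose pipelines break down.

## The model in brief

Every instance is anchored by a peak in a **center heatmap**. Each of
its K keypoints is reached from the center through **two summed offset
hops** guided by a species skeleton grouped into P anatomical parts
(worm 5 keypoints / 5 parts, fish 10/5, fly 26/9):

```
off = off1 + off2          # center -> part point -> keypoint
x_k = s · (c + off1[p(k)] + off2[k])      (s = output stride, 4)
```

The part points are *adaptive*: only the composed displacement is
supervised (single L1 loss), so the network places each part anchor
wherever it helps. Features at the part positions are gathered by
**multi-scale feature sampling** (bilinear warp of channel-standardized
pyramid levels, fused by learned per-part weights) and refined by
**structure-guided learning** — a per-cell transformer over the P part
tokens plus a learnable part-type embedding, which lets parts inform
each other under occlusion. Center and auxiliary keypoint heatmaps are
trained with the penalty-reduced focal loss (α=2, β=4); the keypoint
heatmap branch exists only at training time and decoding provably
never reads it.

Evaluation is COCO-style **OKS** AP/AP50/AP75/AR
(`OKS = Σᵢ exp(−dᵢ²/2s²kᵢ²)·[vᵢ>0] / Σᵢ[vᵢ>0]`). No per-keypoint OKS
constants are published for these species, so built-in schemas use a
uniform k = 0.1: metrics are self-consistent, not comparable across
toolchains.

Everything — including the reverse-mode autodiff engine, convolutions,
deformable convolution, bilinear warping and multi-head attention — is
implemented in NumPy and verified against numeric gradients and
nested-loop oracles, so the package runs anywhere Python runs. A
synthetic scene generator (worm splines, articulated fish, six-legged
flies, exact annotations, seeded occlusion) makes the whole pipeline
trainable and testable without any dataset download.

## Worked example

```python
import structpose as sp

# 20 synthetic worm scenes, 1-4 worms each, with occlusion
scenes = sp.generate_dataset(
    sp.SceneConfig(species="celegans", image_size=(128, 128),
                   n_instances=(1, 4), occlusion_prob=0.3, seed=11), 20)

model_cfg = sp.ModelConfig(schema="celegans", channels=16, head_channels=16,
                           sgl_ffn_dim=32, backbone_widths=(8, 16, 24, 32), seed=1)
train_cfg = sp.TrainConfig(eta0=2e-3, eta_min=1e-4, t_max=200, batch_size=5,
                           seed=2, augment=None)
model, history = sp.train(train_cfg, scenes, model_cfg=model_cfg)

from structpose.train import evaluate_on_samples
print(evaluate_on_samples(model, scenes).summary())
```

After ~10 minutes on one CPU core this prints:

```
AP   (OKS 0.50:0.95)  0.954
AP50                  1.000
AP75                  1.000
AR   (OKS 0.50:0.95)  0.973
```

i.e. the network detects every worm in its training scenes (AP50 = 1)
and localizes keypoints tightly enough to keep 95% mean AP across the
strict OKS threshold sweep — an end-to-end trainability check on
synthetic data, not a benchmark claim.

The same workflow is available from the shell:

```bash
structpose synth --species celegans --n-images 20 --seed 11 --out data/
structpose train --data data/ --epochs 200 --no-augment --out run/
structpose infer --checkpoint run/checkpoint.npz --images data/ --out dets.json
structpose eval  --gt data/annotations.json --dt dets.json --schema celegans
structpose render --checkpoint run/checkpoint.npz --image data/scene_00001.png --out overlay.png
```

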