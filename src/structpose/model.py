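"""The three-branch structure-aware pose network.

A shared backbone pyramid feeds:

1. a center-heatmap head (instance localization),
2. a two-hop regression branch: the Part Perception head regresses
   first-hop offsets from every cell to P adaptive part points; the MFS
   module bilinearly samples channel-standardized pyramid levels at the
   displaced part positions and fuses them; the SGL module lets the P
   part tokens attend to each other per cell; per-part linear heads then
   regress second-hop offsets to each part's own keypoints,
3. an auxiliary keypoint-heatmap head used only during training.

The final center-to-keypoint displacement is the sum of the two hops;
only that sum is supervised, so the split between hops is free and the
part points are learned, not annotated.

Offsets are expressed in output-stride (default 4) pixel units
throughout; decoding rescales to input pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate, grid_sample, stack
from .schema import SkeletonSchema, builtin_schema

__all__ = ["ModelConfig", "StructPoseNet", "LightBackbone", "build_model"]


@dataclass
class ModelConfig:
    schema: str = "celegans"
    backbone_widths: tuple = (16, 32, 48, 64)  # channels at strides 4/8/16/32
    fuse_levels: tuple = (4, 8)     # pyramid strides entering MFS
    ct_variant: str = "ct2"         # "ct1": conv-relu-conv; "ct2": adds BN-relu-deformable conv
    fusion: str = "a_add"           # "a_add" (learned softmax weights) or "con_cat"
    channels: int = 64              # per-part feature dim C after channel transformation
    head_channels: int = 32
    sgl_layers: int = 1
    sgl_ffn_dim: int = 512
    sgl_type_embed: bool = True
    sgl_heads: int = 4
    sgl_raw_qk: bool = False        # literal reading: Q,K = token + embedding, unprojected
    seed: int = 0

    def to_dict(self):
        d = asdict(self)
        d["backbone_widths"] = list(self.backbone_widths)
        d["fuse_levels"] = list(self.fuse_levels)
        return d

    @staticmethod
    def from_dict(d):
        d = dict(d)
        for k in ("backbone_widths", "fuse_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return ModelConfig(**d)


class LightBackbone(nn.Module):
    """A small residual CNN pyramid emitting strides {4, 8, 16, 32}.

    This is the CPU-friendly default provider of the multi-scale feature
    contract; any module returning a dict {stride: (B, C_s, H/s, W/s)}
    with a stride-4 entry can stand in (e.g. an HRNet port).
    """

    def __init__(self, widths=(16, 32, 48, 64), *, rng):
        w0, w1, w2, w3 = widths[0], widths[0], widths[1], widths[2]
        self.widths = dict(zip((4, 8, 16, 32), (widths[0], widths[1], widths[2], widths[3])))
        self.stem1 = nn.Conv2d(3, widths[0], stride=2, rng=rng)
        self.stem2 = nn.Conv2d(widths[0], widths[0], stride=2, rng=rng)
        self.block4a = nn.Conv2d(widths[0], widths[0], rng=rng)
        self.block4b = nn.Conv2d(widths[0], widths[0], rng=rng)
        self.down8 = nn.Conv2d(widths[0], widths[1], stride=2, rng=rng)
        self.block8 = nn.Conv2d(widths[1], widths[1], rng=rng)
        self.down16 = nn.Conv2d(widths[1], widths[2], stride=2, rng=rng)
        self.down32 = nn.Conv2d(widths[2], widths[3], stride=2, rng=rng)

    def forward(self, x: Tensor) -> dict:
        b, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input size {(h, w)} must be divisible by 32")
        s = self.stem2(self.stem1(x).relu()).relu()
        f4 = (s + self.block4b(self.block4a(s).relu())).relu()
        f8 = self.block8(self.down8(f4).relu()).relu()
        f16 = self.down16(f8).relu()
        f32 = self.down32(f16).relu()
        return {4: f4, 8: f8, 16: f16, 32: f32}


class ChTrans(nn.Module):
    """Channel-standardization block for one pyramid level.

    ct1: conv - ReLU - conv.
    ct2: conv - ReLU - conv+BN - ReLU - deformable conv (spatially adaptive).
    """

    def __init__(self, cin, cout, variant="ct2", *, rng):
        self.variant = variant
        if variant == "ct1":
            self.conv1 = nn.Conv2d(cin, cout, rng=rng)
            self.conv2 = nn.Conv2d(cout, cout, rng=rng)
        elif variant == "ct2":
            self.conv1 = nn.Conv2d(cin, cout, rng=rng)
            self.conv2 = nn.Conv2d(cout, cout, rng=rng)
            self.bn = nn.BatchNorm2d(cout)
            self.dcn = nn.DeformConv2d(cout, cout, rng=rng)
        else:
            raise ValueError(f"unknown ct_variant {variant!r}")

    def forward(self, x):
        if self.variant == "ct1":
            return self.conv2(self.conv1(x).relu())
        y = self.bn(self.conv2(self.conv1(x).relu())).relu()
        return self.dcn(y)


class SGLayer(nn.Module):
    """Pre-norm transformer layer over the P part tokens of each cell."""

    def __init__(self, c, ffn_dim, n_heads, raw_qk, *, rng):
        self.ln1 = nn.LayerNorm(c)
        self.mhsa = nn.MultiHeadSelfAttention(c, n_heads=n_heads, raw_qk=raw_qk, rng=rng)
        self.ln2 = nn.LayerNorm(c)
        self.ffn1 = nn.Linear(c, ffn_dim, rng=rng)
        self.ffn2 = nn.Linear(ffn_dim, c, rng=rng)

    def forward(self, x, type_embed=None):
        x = x + self.mhsa(self.ln1(x), qk_extra=type_embed)
        x = x + self.ffn2(self.ffn1(self.ln2(x)).relu())
        return x


class SGL(nn.Module):
    """Structure-guided refinement: per-cell self-attention among parts.

    Tokens at different cells never interact; all cells share weights.
    """

    def __init__(self, n_parts, c, n_layers=1, ffn_dim=512, type_embed=True,
                 n_heads=4, raw_qk=False, *, rng):
        self.type_embed = (
            nn.Parameter(rng.normal(0.0, 0.02, size=(n_parts, c))) if type_embed else None
        )
        self.layers = [
            SGLayer(c, ffn_dim, n_heads, raw_qk, rng=rng) for _ in range(n_layers)
        ]

    def forward(self, tokens: Tensor) -> Tensor:
        """tokens: (B, N_cells, P, C) -> same shape, refined."""
        for layer in self.layers:
            tokens = layer(tokens, type_embed=self.type_embed)
        return tokens


class StructPoseNet(nn.Module):
    def __init__(self, schema: SkeletonSchema, cfg: ModelConfig, backbone=None):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.schema = schema
        p, k, c = schema.n_parts, schema.n_keypoints, cfg.channels
        self.backbone = backbone or LightBackbone(cfg.backbone_widths, rng=rng)
        widths = self.backbone.widths
        f4c = widths[4]
        hc = cfg.head_channels
        self.center_head = nn.Sequential(
            nn.Conv2d(f4c, hc, rng=rng), nn.ReLU(), nn.Conv2d(hc, 1, k=1, rng=rng)
        )
        self.kp_head = nn.Sequential(
            nn.Conv2d(f4c, hc, rng=rng), nn.ReLU(), nn.Conv2d(hc, k, k=1, rng=rng)
        )
        # heatmap logits start at a low prior probability (~0.01) so the
        # focal losses are not swamped by the background early on
        self.center_head.layers[-1].bias.data[:] = -4.6
        self.kp_head.layers[-1].bias.data[:] = -4.6
        # Part Perception reads the raw stride-4 level
        self.part_perception = nn.Sequential(
            nn.Conv2d(f4c, hc, rng=rng), nn.ReLU(), nn.Conv2d(hc, 2 * p, k=1, rng=rng)
        )
        self.part_perception.layers[-1].weight.data *= 0.1  # start near zero offsets
        self.ch_trans = {
            s: ChTrans(widths[s], c, cfg.ct_variant, rng=rng) for s in cfg.fuse_levels
        }
        self.ct_list = list(self.ch_trans.values())  # parameter + state discovery
        if cfg.fusion == "a_add":
            self.fuse_logits = nn.Parameter(np.zeros((p, len(cfg.fuse_levels))))
        elif cfg.fusion == "con_cat":
            self.fuse_mix = nn.Linear(c * len(cfg.fuse_levels), c, rng=rng)
        else:
            raise ValueError(f"unknown fusion {cfg.fusion!r}")
        self.sgl = SGL(
            p, c, cfg.sgl_layers, cfg.sgl_ffn_dim, cfg.sgl_type_embed,
            cfg.sgl_heads, cfg.sgl_raw_qk, rng=rng,
        )
        # one linear head per part, mapping its refined feature to the
        # (dx, dy) of each keypoint it owns: ownership is structural
        self.off2_heads = [
            nn.Linear(c, 2 * len(part.keypoint_indices), rng=rng) for part in schema.parts
        ]
        for head in self.off2_heads:
            head.weight.data *= 0.1
        kp_order = [ki for part in schema.parts for ki in part.keypoint_indices]
        chan_order = []
        for ki in kp_order:
            chan_order += [2 * ki, 2 * ki + 1]
        self._off2_chan_perm = np.argsort(chan_order)

    # -- pieces ------------------------------------------------------------

    def mfs(self, features: dict, off1: Tensor) -> Tensor:
        """Sample + fuse pyramid features at part-point positions.

        features: {stride: (B, C_s, h_s, w_s)}; off1: (B, 2P, h, w) in
        stride-4 cell units. Returns part features (B, P, C, h, w).
        Out-of-grid samples are border-clamped by the sampler.
        """
        cfg = self.cfg
        p = self.schema.n_parts
        f4 = features[4]
        b, _, h, w = f4.shape
        trans = {s: self.ch_trans[s](features[s]) for s in cfg.fuse_levels}
        jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        base = np.stack([jj.ravel(), ii.ravel()], axis=-1)[None]  # (1, hw, 2)
        if cfg.fusion == "a_add":
            fuse_w = self.fuse_logits.softmax(axis=-1)  # (P, L)
        part_feats = []
        for pi in range(p):
            offp = off1[:, 2 * pi : 2 * pi + 2].reshape(b, 2, h * w).transpose(0, 2, 1)
            pos = offp + base  # stride-4 cell coordinates
            sampled = []
            for s in cfg.fuse_levels:
                coords = pos * (4.0 / s)
                sampled.append(grid_sample(trans[s], coords))  # (B, C, hw)
            if cfg.fusion == "a_add":
                fused = None
                for li, smp in enumerate(sampled):
                    term = smp * fuse_w[pi, li].reshape(1, 1, 1)
                    fused = term if fused is None else fused + term
            else:
                cat = concatenate(sampled, axis=1).transpose(0, 2, 1)  # (B, hw, C*L)
                fused = self.fuse_mix(cat).transpose(0, 2, 1)
            part_feats.append(fused)
        fpt = stack(part_feats, axis=1)  # (B, P, C, hw)
        return fpt.reshape(b, p, cfg.channels, h, w)

    def sgl_refine(self, fpt: Tensor) -> Tensor:
        """(B, P, C, h, w) -> structurally refined, same shape."""
        b, p, c, h, w = fpt.shape
        tokens = fpt.reshape(b, p, c, h * w).transpose(0, 3, 1, 2)  # (B, hw, P, C)
        refined = self.sgl(tokens)
        return refined.transpose(0, 2, 3, 1).reshape(b, p, c, h, w)

    def off2_from_parts(self, refined: Tensor) -> Tensor:
        """Per-part heads -> (B, 2K, h, w) second-hop offset field."""
        b, p, c, h, w = refined.shape
        outs = []
        for pi, head in enumerate(self.off2_heads):
            tok = refined[:, pi].reshape(b, c, h * w).transpose(0, 2, 1)  # (B, hw, C)
            outs.append(head(tok).transpose(0, 2, 1))  # (B, 2Kp, hw)
        off2 = concatenate(outs, axis=1)  # part-ordered channels
        off2 = off2[:, self._off2_chan_perm]
        return off2.reshape(b, -1, h, w)

    # -- full forward ------------------------------------------------------

    def forward(self, x: Tensor, train: bool = True) -> dict:
        feats = self.backbone(x)
        f4 = feats[4]
        center = self.center_head(f4).sigmoid()
        off1 = self.part_perception(f4)
        fpt = self.mfs(feats, off1)
        refined = self.sgl_refine(fpt)
        off2 = self.off2_from_parts(refined)
        out = {
            "center_heatmap": center,
            "off1_field": off1,
            "off2_field": off2,
            "part_features": fpt,
            "refined_part_features": refined,
        }
        if train:
            out["keypoint_heatmaps"] = self.kp_head(f4).sigmoid()
        return out

    def predict(self, image: np.ndarray, train: bool = False) -> dict:
        """Numpy-in / numpy-out forward in eval mode (no gradient tape)."""
        was_training = self.training
        self.eval()
        x = Tensor(np.ascontiguousarray(image.transpose(2, 0, 1))[None])
        out = self.forward(x, train=train)
        self.train(was_training)
        return {k: v.data[0] for k, v in out.items()}


def build_model(cfg: ModelConfig, schema: SkeletonSchema | None = None) -> StructPoseNet:
    schema = schema or builtin_schema(cfg.schema)
    if schema.n_parts < 1:
        raise ValueError("schema has no parts")
    return StructPoseNet(schema, cfg)


def save_checkpoint(model: StructPoseNet, path) -> None:
    """Single-file checkpoint: weights + config echo (npz)."""
    import json

    state = model.state_dict()
    np.savez(path, __config__=json.dumps(model.cfg.to_dict()), **state)


def load_checkpoint(path) -> StructPoseNet:
    import json

    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
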