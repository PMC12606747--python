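"""Network structure: shapes, MFS against a nested-loop oracle, SGL
contracts, ownership routing, train/infer equivalence, gradient flow."""

import numpy as np
import pytest

import structpose as sp
from structpose import nn
from structpose.autodiff import Tensor
from structpose.model import ChTrans, LightBackbone, ModelConfig, SGL, build_model


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestBackbone:
    def test_pyramid_shapes(self, tiny_model):
        x = Tensor(_rng().normal(size=(1, 3, 128, 128)))
        feats = tiny_model.backbone(x)
        assert feats[4].shape == (1, 8, 32, 32)
        assert feats[8].shape == (1, 12, 16, 16)
        assert feats[16].shape == (1, 16, 8, 8)
        assert feats[32].shape == (1, 16, 4, 4)

    def test_indivisible_size_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.backbone(Tensor(np.zeros((1, 3, 100, 100))))

    def test_deterministic_given_seed(self):
        a = LightBackbone((8, 12, 16, 16), rng=_rng(5))
        b = LightBackbone((8, 12, 16, 16), rng=_rng(5))
        x = Tensor(np.zeros((1, 3, 64, 64)))
        assert np.array_equal(a(x)[4].data, b(x)[4].data)


class TestHeads:
    @pytest.mark.parametrize("species,p,k", [("celegans", 5, 5), ("drosophila", 9, 26)])
    def test_offset_channel_counts(self, species, p, k):
        cfg = ModelConfig(schema=species, channels=8, head_channels=8, sgl_ffn_dim=16,
                          backbone_widths=(8, 8, 8, 8), sgl_heads=2, seed=0)
        model = build_model(cfg)
        out = model.forward(Tensor(np.zeros((1, 3, 64, 64))), train=True)
        assert out["off1_field"].shape[1] == 2 * p
        assert out["off2_field"].shape[1] == 2 * k
        assert out["keypoint_heatmaps"].shape[1] == k

    def test_zero_weight_part_head_gives_zero_offsets(self, tiny_model):
        for layer in tiny_model.part_perception.layers:
            if hasattr(layer, "weight"):
                layer.weight.data[:] = 0.0
                layer.bias.data[:] = 0.0
        out = tiny_model.forward(Tensor(_rng().normal(size=(1, 3, 64, 64))), train=False)
        assert np.abs(out["off1_field"].data).max() == 0.0

    def test_train_and_infer_modes_agree(self, worm_scene):
        cfg = ModelConfig(schema="celegans", channels=16, head_channels=8, sgl_ffn_dim=32,
                          backbone_widths=(8, 12, 16, 16), seed=9)
        model = build_model(cfg).eval()
        x = Tensor(worm_scene.image.transpose(2, 0, 1)[None])
        out_t = model.forward(x, train=True)
        out_i = model.forward(x, train=False)
        assert "keypoint_heatmaps" not in out_i
        for key in ("center_heatmap", "off1_field", "off2_field"):
            assert np.array_equal(out_t[key].data, out_i[key].data)


class TestMFS:
    def _mfs_oracle(self, levels, off1, weights, n_parts):
        """Nested-loop bilinear sampling + per-part weighted sum."""
        b = levels[0].shape[0]
        c = levels[0].shape[1]
        h, w = levels[0].shape[2:]
        out = np.zeros((b, n_parts, c, h, w))
        strides = [4 * levels[0].shape[2] // lv.shape[2] for lv in levels]
        for bi in range(b):
            for p in range(n_parts):
                for i in range(h):
                    for j in range(w):
                        px = j + off1[bi, 2 * p, i, j]
                        py = i + off1[bi, 2 * p + 1, i, j]
                        acc = np.zeros(c)
                        for li, lv in enumerate(levels):
                            scale = 4.0 / strides[li]
                            hh, ww = lv.shape[2:]
                            x = min(max(px * scale, 0.0), ww - 1.0)
                            y = min(max(py * scale, 0.0), hh - 1.0)
                            x0 = min(int(np.floor(x)), ww - 2) if ww > 1 else 0
                            y0 = min(int(np.floor(y)), hh - 2) if hh > 1 else 0
                            tx, ty = x - x0, y - y0
                            val = (
                                lv[bi, :, y0, x0] * (1 - ty) * (1 - tx)
                                + lv[bi, :, y0, x0 + 1] * (1 - ty) * tx
                                + lv[bi, :, y0 + 1, x0] * ty * (1 - tx)
                                + lv[bi, :, y0 + 1, x0 + 1] * ty * tx
                            )
                            acc += weights[p, li] * val
                        out[bi, p, :, i, j] = acc
        return out

    def _identity_mfs_model(self, n_levels=2):
        """Worm model whose channel transforms are identity (ct1 with
        identity convs) so MFS output is directly comparable."""
        cfg = ModelConfig(schema="celegans", channels=3, head_channels=4, sgl_ffn_dim=8,
                          backbone_widths=(3, 3, 3, 3), ct_variant="ct1",
                          fuse_levels=(4, 8)[:n_levels], sgl_heads=1, seed=0)
        model = build_model(cfg)
        for ct in model.ch_trans.values():
            for conv in (ct.conv1, ct.conv2):
                conv.weight.data[:] = 0.0
                conv.bias.data[:] = 0.0
                for i in range(3):
                    conv.weight.data[i, i, 1, 1] = 1.0
        return model

    def test_zero_offset_single_level_equals_direct_lookup(self):
        model = self._identity_mfs_model(n_levels=1)
        feats = {4: Tensor(np.abs(_rng(3).normal(size=(1, 3, 8, 8))))}
        off1 = Tensor(np.zeros((1, 10, 8, 8)))
        fpt = model.mfs(feats, off1)
        for p in range(5):
            assert np.array_equal(fpt.data[0, p], feats[4].data[0])

    def test_ramp_sampling_is_exact(self):
        """Bilinear interpolation of g(x,y)=x at x=2.5 gives exactly 2.5."""
        model = self._identity_mfs_model(n_levels=1)
        ramp = np.tile(np.arange(8.0), (8, 1))
        feats = {4: Tensor(np.broadcast_to(ramp, (1, 3, 8, 8)).copy())}
        off1 = np.zeros((1, 10, 8, 8))
        off1[:, 0::2] = 0.5  # +0.5 cell in x for every part
        fpt = model.mfs(feats, Tensor(off1))
        assert fpt.data[0, 0, 0, 3, 2] == pytest.approx(2.5)

    def test_matches_nested_loop_oracle(self):
        rng = _rng(11)
        model = self._identity_mfs_model(n_levels=2)
        # positive features: the identity channel transform still passes
        # through an interior ReLU
        f4 = np.abs(rng.normal(size=(2, 3, 8, 8)))
        f8 = np.abs(rng.normal(size=(2, 3, 4, 4)))
        off1 = rng.normal(scale=2.0, size=(2, 10, 8, 8))
        logits = rng.normal(size=(5, 2))
        model.fuse_logits.data[:] = logits
        weights = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        fpt = model.mfs({4: Tensor(f4), 8: Tensor(f8)}, Tensor(off1))
        oracle = self._mfs_oracle([f4, f8], off1, weights, n_parts=5)
        assert np.abs(fpt.data - oracle).max() < 1e-5

    def test_out_of_grid_sampling_is_border_clamped(self):
        model = self._identity_mfs_model(n_levels=1)
        feats = {4: Tensor(_rng(4).normal(size=(1, 3, 8, 8)))}
        off1 = Tensor(np.full((1, 10, 8, 8), 100.0))
        fpt = model.mfs(feats, off1)
        assert np.isfinite(fpt.data).all()
        assert fpt.data[0, 0, 0, 0, 0] == pytest.approx(feats.data if False else feats[4].data[0, 0, 7, 7])


class TestSGL:
    def _tokens(self, b=2, cells=3, p=5, c=16, seed=0):
        return Tensor(_rng(seed).normal(size=(b, cells, p, c)))

    def test_attention_rows_sum_to_one(self):
        mh = nn.MultiHeadSelfAttention(16, n_heads=4, rng=_rng(1))
        _, attn = mh(self._tokens(), return_attn=True)
        sums = attn.data.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_cell_independence(self):
        """Identical token sets at two cells refine identically."""
        sgl = SGL(5, 16, rng=_rng(2))
        tok = self._tokens(b=1, cells=4)
        tok.data[0, 2] = tok.data[0, 0]
        out = sgl(tok)
        assert np.allclose(out.data[0, 2], out.data[0, 0], atol=1e-12)

    def test_residual_identity_with_zeroed_projections(self):
        sgl = SGL(5, 16, rng=_rng(3))
        layer = sgl.layers[0]
        layer.mhsa.wo.weight.data[:] = 0.0
        layer.mhsa.wo.bias.data[:] = 0.0
        layer.ffn2.weight.data[:] = 0.0
        layer.ffn2.bias.data[:] = 0.0
        tok = self._tokens(seed=4)
        out = sgl(tok)
        assert np.array_equal(out.data, tok.data)

    def test_part_permutation_equivariance(self):
        """Without type embeddings the refinement commutes with part
        reordering; with them, permuting the embeddings restores it."""
        perm = np.array([3, 1, 4, 0, 2])
        tok = self._tokens(seed=5)
        sgl_plain = SGL(5, 16, type_embed=False, rng=_rng(6))
        a = sgl_plain(Tensor(tok.data[:, :, perm])).data
        b = sgl_plain(tok).data[:, :, perm]
        assert np.allclose(a, b, atol=1e-10)
        sgl_embed = SGL(5, 16, type_embed=True, rng=_rng(6))
        out1 = sgl_embed(tok).data[:, :, perm]
        sgl_embed.type_embed.data = sgl_embed.type_embed.data[perm]
        out2 = sgl_embed(Tensor(tok.data[:, :, perm])).data
        assert np.allclose(out1, out2, atol=1e-10)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            nn.MultiHeadSelfAttention(10, n_heads=4, rng=_rng(0))


class TestRouting:
    def test_zeroing_part_features_touches_only_owned_keypoints(self, tiny_model):
        """Keypoint ownership is structural: part p's refined features
        feed only the off2 channels of p's own keypoints."""
        schema = tiny_model.schema
        rng = _rng(8)
        refined = Tensor(rng.normal(size=(1, 5, 16, 8, 8)))
        base = tiny_model.off2_from_parts(refined).data
        for p, part in enumerate(schema.parts):
            ablated = refined.data.copy()
            ablated[:, p] = 0.0
            out = tiny_model.off2_from_parts(Tensor(ablated)).data
            changed = {
                n for n in range(schema.n_keypoints)
                if not np.allclose(out[:, 2 * n : 2 * n + 2], base[:, 2 * n : 2 * n + 2])
            }
            assert changed <= set(part.keypoint_indices)


class TestGradientFlow:
    def test_each_loss_reaches_backbone(self, worm_scene, worm_schema):
        """Each branch loss alone produces nonzero backbone gradients."""
        from structpose import losses as L

        cfg = ModelConfig(schema="celegans", channels=8, head_channels=8, sgl_ffn_dim=16,
                          backbone_widths=(8, 8, 8, 8), sgl_heads=2, seed=1)
        model = build_model(cfg)
        t = sp.encode_targets(worm_scene.instances, worm_schema, (128, 128), 4)
        x = Tensor(worm_scene.image.transpose(2, 0, 1)[None])
        probe = model.backbone.stem1.weight

        def run(which):
            model.zero_grad()
            out = model.forward(x, train=True)
            if which == "hm":
                loss = L.center_focal_loss(out["center_heatmap"], t.center_heatmap[None], t.n_pos_centers)
            elif which == "hp":
                pred, tgt, mask = L.gather_predicted_offsets(
                    out["off1_field"], out["off2_field"], [t], model.schema.part_of_keypoint()
                )
                loss = L.offset_l1_loss(pred, tgt, mask)
            else:
                loss = L.keypoint_focal_loss(out["keypoint_heatmaps"], t.keypoint_heatmaps[None], t.n_pos_keypoints)
            loss.backward()
            return np.linalg.norm(probe.grad)

        assert run("hm") > 0
        assert run("hp") > 0
        assert run("hm_hp") > 0


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_model, worm_scene):
        from structpose.model import load_checkpoint, save_checkpoint

        path = tmp_path / "ckpt.npz"
        save_checkpoint(tiny_model, path)
        clone = load_checkpoint(path)
        a = tiny_model.predict(worm_scene.image)
        b = clone.predict(worm_scene.image)
        assert np.array_equal(a["center_heatmap"], b["center_heatmap"])
        assert np.array_equal(a["off2_field"], b["off2_field"])
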