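"""Network components against hand-computed oracles, limit behaviors,
the printed shape ladder, and ablation-variant integrity."""

import numpy as np
import pytest

import mammofusion as mf
from mammofusion.model import (Branch, ClassificationHead, ConcatFusion,
                               GatedFusion, MammoFusionNet, ModelConfig,
                               ResidualBlock, SpatialAttention, TABLE_VARIANTS,
                               gated_fuse, load_checkpoint)
from mammofusion.nn import MultiHeadSelfAttention, Tensor, autograd as ag
from mammofusion.training import weighted_bce


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# residual blocks and branches
# ---------------------------------------------------------------------------

class TestResidualBlock:
    def test_zero_main_path_reduces_to_shortcut(self, rng):
        block = ResidualBlock(2, 3, rng)
        block.conv.w.data[...] = 0.0
        block.conv.b.data[...] = 0.0
        x = Tensor(rng.random((1, 4, 4, 2)).astype(np.float32))
        out = block(x)
        short = block.shortcut(x)
        # main path is ReLU(BN(0)) = 0 pooled = 0, so output == shortcut
        assert np.allclose(out.data, short.data, atol=1e-6)

    def test_hand_computed_toy_block(self):
        """4x4 single-channel input, 1-filter conv, inference-mode batch
        norm with unit statistics: output equals conv -> ReLU -> pool plus
        the strided 1x1 shortcut, computed by hand with numpy."""
        rng = np.random.default_rng(0)
        block = ResidualBlock(1, 1, rng)
        kernel = np.arange(9, dtype=np.float32).reshape(3, 3) / 10.0
        block.conv.w.data[...] = kernel[:, :, None, None]
        block.conv.b.data[...] = 0.5
        block.shortcut.w.data[...] = 2.0
        block.bn.eval()
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1) / 4.0

        from scipy import ndimage
        conv = ndimage.correlate(x[0, :, :, 0], kernel, mode="constant") + 0.5
        bn = conv / np.sqrt(1.0 + 1e-5)  # running mean 0, var 1
        relu = np.maximum(bn, 0.0)
        pooled = relu.reshape(2, 2, 2, 2).transpose(0, 2, 1, 3).reshape(2, 2, 4).max(-1)
        shortcut = 2.0 * x[0, ::2, ::2, 0]
        expected = pooled + shortcut

        out = block(Tensor(x)).data[0, :, :, 0]
        assert np.allclose(out, expected, atol=1e-5)

    def test_block1_shape(self, rng):
        block = ResidualBlock(1, 32, rng)
        out = block(Tensor(np.zeros((1, 256, 256, 1), dtype=np.float32)))
        assert out.shape == (1, 128, 128, 32)


class TestBranch:
    def test_shape_ladder(self, rng):
        branch = Branch(rng, 256)
        stages = {}
        out = branch(Tensor(np.zeros((1, 256, 256, 1), dtype=np.float32)), stages)
        assert stages["block1"].shape == (1, 128, 128, 32)
        assert stages["block2"].shape == (1, 64, 64, 64)
        assert stages["block3"].shape == (1, 32, 32, 128)
        assert out.shape == (1, 32, 32, 128)

    def test_wrong_input_size_rejected(self, rng):
        branch = Branch(rng, 256)
        with pytest.raises(ValueError, match="256x256x1"):
            branch(Tensor(np.zeros((1, 64, 64, 1), dtype=np.float32)))

    def test_zero_input_zero_biases_gives_zero_output(self, rng):
        branch = Branch(rng, 64)
        branch.eval()
        for name, p in branch.named_parameters().items():
            if name.endswith(".b") or name.endswith("beta"):
                p.data[...] = 0.0
        out = branch(Tensor(np.zeros((1, 64, 64, 1), dtype=np.float32)))
        assert np.allclose(out.data, 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestGatedFusion:
    def test_zero_weights_give_half_gates(self, rng):
        fusion = GatedFusion(3, rng)
        for p in fusion.parameters():
            p.data[...] = 0.0
        f = Tensor(rng.random((1, 2, 2, 3)).astype(np.float32))
        g_mlo, g_cc = fusion.compute_gates(f, f)
        assert np.allclose(g_mlo.data, 0.5, atol=1e-7)
        assert np.allclose(g_cc.data, 0.5, atol=1e-7)

    def test_large_bias_saturates_gates(self, rng):
        fusion = GatedFusion(3, rng)
        for p in fusion.parameters():
            p.data[...] = 0.0
        fusion.gate_mlo.b.data[...] = 10.0
        f = Tensor(rng.random((1, 2, 2, 3)).astype(np.float32))
        g_mlo, _ = fusion.compute_gates(f, f)
        assert (g_mlo.data > 0.999).all()

    def test_toy_gate_values_match_scalar_sigmoid(self, rng):
        fusion = GatedFusion(3, rng)
        w = rng.standard_normal((1, 1, 3, 3)).astype(np.float32)
        b = rng.standard_normal(3).astype(np.float32)
        fusion.gate_mlo.w.data[...] = w
        fusion.gate_mlo.b.data[...] = b
        f = rng.random((1, 2, 2, 3)).astype(np.float32)
        g_mlo, _ = fusion.compute_gates(Tensor(f), Tensor(f))
        expected = sigmoid(f @ w[0, 0] + b)
        assert np.allclose(g_mlo.data, expected, atol=1e-6)

    def test_saturated_gates_reproduce_single_view(self, rng):
        f_mlo = Tensor(rng.random((1, 2, 2, 4)).astype(np.float32))
        f_cc = Tensor(rng.random((1, 2, 2, 4)).astype(np.float32))
        ones, zeros = Tensor(np.ones(f_mlo.shape)), Tensor(np.zeros(f_mlo.shape))
        fused = gated_fuse(f_mlo, f_cc, ones, zeros)
        assert np.array_equal(fused.data, f_mlo.data)

    def test_half_gates_reconstruct_shared_feature(self, rng):
        f = Tensor(rng.random((1, 2, 2, 4)).astype(np.float32))
        halves = Tensor(np.full(f.shape, 0.5))
        fused = gated_fuse(f, f, halves, halves)
        assert np.allclose(fused.data, f.data, atol=1e-7)

    def test_fusion_matches_elementwise_loop(self, rng):
        shapes = (1, 2, 2, 2)
        fm, fc, gm, gc = (rng.random(shapes).astype(np.float32) for _ in range(4))
        fused = gated_fuse(Tensor(fm), Tensor(fc), Tensor(gm), Tensor(gc)).data
        for idx in np.ndindex(*shapes):
            expected = gm[idx] * fm[idx] + gc[idx] * fc[idx]
            assert abs(fused[idx] - expected) < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        a = Tensor(np.zeros((1, 2, 2, 3), dtype=np.float32))
        b = Tensor(np.zeros((1, 4, 4, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="differ"):
            gated_fuse(a, b, a, a)


class TestConcatFusion:
    def test_output_channel_count(self, rng):
        fusion = ConcatFusion(8, rng)
        f = Tensor(rng.random((2, 4, 4, 8)).astype(np.float32))
        assert fusion(f, f).shape == (2, 4, 4, 8)

    def test_identity_selection_returns_first_view(self, rng):
        fusion = ConcatFusion(4, rng)
        fusion.reduce.w.data[...] = 0.0
        fusion.reduce.b.data[...] = 0.0
        fusion.reduce.w.data[0, 0, :4, :] = np.eye(4)  # select the MLO half
        f_mlo = Tensor(rng.random((1, 3, 3, 4)).astype(np.float32))
        f_cc = Tensor(rng.random((1, 3, 3, 4)).astype(np.float32))
        out = fusion(f_mlo, f_cc)
        assert np.allclose(out.data, f_mlo.data, atol=1e-6)

    def test_matches_hand_computed_1x1_conv(self, rng):
        fusion = ConcatFusion(2, rng)
        w = rng.standard_normal((1, 1, 4, 2)).astype(np.float32)
        b = rng.standard_normal(2).astype(np.float32)
        fusion.reduce.w.data[...] = w
        fusion.reduce.b.data[...] = b
        fm = rng.random((1, 2, 2, 2)).astype(np.float32)
        fc = rng.random((1, 2, 2, 2)).astype(np.float32)
        out = fusion(Tensor(fm), Tensor(fc)).data
        expected = np.concatenate([fm, fc], axis=-1) @ w[0, 0] + b
        assert np.allclose(out, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class TestMultiHeadSelfAttention:
    def test_single_token_attention_weight_is_one(self, rng):
        mhsa = MultiHeadSelfAttention(8, 2, rng)
        x = Tensor(rng.random((1, 1, 8)).astype(np.float32))
        out = mhsa(x)
        assert np.allclose(mhsa.last_attention_weights, 1.0)
        # pre-residual output = W_o(W_v x) when only one token attends to itself
        v = x.data @ mhsa.wv.w.data + mhsa.wv.b.data
        expected = v @ mhsa.wo.w.data + mhsa.wo.b.data
        assert np.allclose(out.data, expected, atol=1e-5)

    def test_identical_tokens_give_identical_outputs(self, rng):
        mhsa = MultiHeadSelfAttention(8, 4, rng)
        token = rng.random(8).astype(np.float32)
        x = Tensor(np.tile(token, (1, 5, 1)))
        out = mhsa(x).data
        assert np.allclose(out, out[:, :1, :], atol=1e-6)

    def test_two_token_two_head_hand_oracle(self, rng):
        """2 tokens, 4 channels, 2 heads: attention weights and outputs
        equal a from-scratch numpy computation of softmax(QK^T/sqrt(2))V."""
        mhsa = MultiHeadSelfAttention(4, 2, rng)
        x = rng.standard_normal((1, 2, 4)).astype(np.float32)
        out = mhsa(Tensor(x)).data

        def proj(layer):
            return x[0] @ layer.w.data + layer.b.data

        q, k, v = proj(mhsa.wq), proj(mhsa.wk), proj(mhsa.wv)
        heads = []
        for h in range(2):
            sl = slice(2 * h, 2 * h + 2)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(2.0)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            attn = e / e.sum(axis=1, keepdims=True)
            assert np.allclose(attn, mhsa.last_attention_weights[0, h], atol=1e-5)
            heads.append(attn @ v[:, sl])
        expected = np.concatenate(heads, axis=1) @ mhsa.wo.w.data + mhsa.wo.b.data
        assert np.allclose(out[0], expected, atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        mhsa = MultiHeadSelfAttention(16, 4, rng)
        mhsa(Tensor(rng.standard_normal((2, 9, 16)).astype(np.float32)))
        sums = mhsa.last_attention_weights.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_indivisible_head_count_rejected(self, rng):
        with pytest.raises(ValueError, match="divide"):
            MultiHeadSelfAttention(10, 4, rng)


class TestSpatialAttention:
    def test_zero_weights_halve_activations(self, rng):
        sa = SpatialAttention(rng)
        sa.conv.w.data[...] = 0.0
        sa.conv.b.data[...] = 0.0
        f = Tensor(rng.random((1, 4, 4, 3)).astype(np.float32))
        stages = {}
        out = sa(f, stages=stages)
        assert np.allclose(stages["m_s"].data, 0.5, atol=1e-7)
        assert np.allclose(out.data, 0.5 * f.data, atol=1e-7)

    def test_channel_constant_input_mean_equals_max(self, rng):
        sa = SpatialAttention(rng)
        plane = rng.random((1, 4, 4, 1)).astype(np.float32)
        f = Tensor(np.repeat(plane, 5, axis=-1))
        avg = ag.tmean(f, axis=3, keepdims=True)
        mx = ag.amax(f, axis=3, keepdims=True)
        assert np.allclose(avg.data, mx.data, atol=1e-7)

    def test_attention_map_matches_direct_convolution(self, rng):
        from scipy import ndimage

        sa = SpatialAttention(rng)
        kernel = rng.standard_normal((7, 7, 2, 1)).astype(np.float32)
        sa.conv.w.data[...] = kernel
        sa.conv.b.data[...] = 0.25
        f = rng.random((1, 8, 8, 4)).astype(np.float32)
        m_s = sa.attention_map(Tensor(f)).data[0, :, :, 0]
        avg, mx = f[0].mean(axis=-1), f[0].max(axis=-1)
        direct = (ndimage.correlate(avg, kernel[:, :, 0, 0], mode="constant")
                  + ndimage.correlate(mx, kernel[:, :, 1, 0], mode="constant")
                  + 0.25)
        assert np.allclose(m_s, sigmoid(direct), atol=1e-5)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

class TestClassificationHead:
    def test_gap_of_channelwise_constants(self, rng):
        from mammofusion.nn import global_average_pool

        consts = rng.random(6).astype(np.float32)
        f = Tensor(np.broadcast_to(consts, (1, 4, 4, 6)).copy())
        assert np.allclose(global_average_pool(f).data[0], consts, atol=1e-6)

    def test_zero_weights_give_half_probability(self, rng):
        head = ClassificationHead(8, 0.5, rng)
        for p in head.parameters():
            p.data[...] = 0.0
        head.eval()
        out = head(Tensor(rng.random((3, 2, 2, 8)).astype(np.float32)))
        assert np.allclose(out.data, 0.5, atol=1e-7)

    def test_miniature_head_matches_scalar_arithmetic(self, rng):
        head = ClassificationHead(2, 0.5, rng)
        head.eval()
        w1 = rng.standard_normal((2, 64)).astype(np.float32)
        w2 = rng.standard_normal((64, 1)).astype(np.float32)
        head.fc1.w.data[...] = w1
        head.fc1.b.data[...] = 0.1
        head.fc2.w.data[...] = w2
        head.fc2.b.data[...] = -0.2
        f = rng.random((1, 2, 2, 2)).astype(np.float32)
        gap = f.mean(axis=(1, 2))
        hidden = np.maximum(gap @ w1 + 0.1, 0.0)
        expected = sigmoid(hidden @ w2 - 0.2)
        assert np.allclose(head(Tensor(f)).data, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class TestMammoFusionNet:
    def test_summary_reports_printed_shape_ladder(self):
        net = MammoFusionNet(ModelConfig(seed=0))
        stages = net.summary()["stages"]
        assert stages["input"] == [256, 256, 1]
        assert stages["branch.block1"] == [128, 128, 32]
        assert stages["branch.block2"] == [64, 64, 64]
        assert stages["branch.block3"] == [32, 32, 128]
        assert stages["f_fused"] == [32, 32, 128]
        assert stages["gap"] == [128]
        assert stages["hidden"] == [64]
        assert stages["prob"] == [1]

    def test_output_in_unit_interval_and_deterministic(self, rng):
        net = MammoFusionNet(ModelConfig(seed=3, input_size=32))
        net.eval()
        cc = rng.random((2, 32, 32)).astype(np.float32)
        mlo = rng.random((2, 32, 32)).astype(np.float32)
        p1 = net(cc, mlo).data
        p2 = net(cc, mlo).data
        assert ((p1 > 0) & (p1 < 1)).all()
        assert np.array_equal(p1, p2)

    def test_prediction_symmetric_under_tied_branches_and_gates(self, rng):
        """With CC-branch weights copied into the MLO branch and tied
        symmetric gates, swapping the two inputs leaves the output
        unchanged (the architecture is view-symmetric up to weights)."""
        net = MammoFusionNet(ModelConfig(seed=5, input_size=32))
        net.eval()
        cc_params = net.branch_cc.named_parameters()
        for name, p in net.branch_mlo.named_parameters().items():
            p.data[...] = cc_params[name].data
        cc_buf = net.branch_cc.named_buffers()
        for name, b in net.branch_mlo.named_buffers().items():
            b[...] = cc_buf[name]
        gcc = net.fusion.gate_cc.named_parameters()
        for name, p in net.fusion.gate_mlo.named_parameters().items():
            p.data[...] = gcc[name].data
        a = rng.random((1, 32, 32)).astype(np.float32)
        b = rng.random((1, 32, 32)).astype(np.float32)
        assert np.allclose(net(a, b).data, net(b, a).data, atol=1e-6)

    @pytest.mark.parametrize("variant", TABLE_VARIANTS,
                             ids=["concat", "gated", "gated+mhsa", "full"])
    def test_ablation_variants_run_forward_backward(self, variant, rng):
        fusion_mode, use_mhsa, use_sa = variant
        net = MammoFusionNet(ModelConfig(
            fusion_mode=fusion_mode, use_mhsa=use_mhsa,
            use_spatial_attention=use_sa, input_size=32, seed=1))
        net.train()
        cc = rng.random((4, 32, 32)).astype(np.float32)
        mlo = rng.random((4, 32, 32)).astype(np.float32)
        prob = net(cc, mlo)
        loss = weighted_bce(np.array([0, 1, 0, 1], dtype=np.float32), prob)
        loss.backward()
        for name, p in net.named_parameters().items():
            assert p.grad is not None and np.linalg.norm(p.grad) > 0, \
                f"no gradient reached {name}"

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = MammoFusionNet(ModelConfig(seed=2, input_size=32))
        net.eval()
        cc = rng.random((1, 32, 32)).astype(np.float32)
        mlo = rng.random((1, 32, 32)).astype(np.float32)
        before = net(cc, mlo).data
        path = tmp_path / "ckpt.npz"
        net.save(path)
        clone = load_checkpoint(path)
        assert np.array_equal(clone(cc, mlo).data, before)
        assert clone.config == net.config

    def test_mlo_and_cc_branches_have_independent_weights(self):
        net = MammoFusionNet(ModelConfig(seed=0, input_size=32))
        w_mlo = net.branch_mlo.block1.conv.w.data
        w_cc = net.branch_cc.block1.conv.w.data
        assert not np.array_equal(w_mlo, w_cc)
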