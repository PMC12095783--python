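"""Feature blocks vs independent scalar-loop oracles, plus contracts.

Every oracle below recomputes the block from the module's weights with
explicit Python loops (no autograd, no vectorized convolution), so a
match at 1e-6 certifies the vectorized implementation.
"""

import numpy as np
import pytest

from btc.features import (
    AttentionConfig,
    ChannelAttentionBlock,
    DenseBlock,
    DenseBlockConfig,
    FeatureExtractor,
    FeatureNetConfig,
    MultiScaleBlock,
    SelfAttentionBlock,
    SpatialAttentionBlock,
    Transition,
    aggregate_attention,
    channel_attention,
    dense_block,
    extract_feature_vector,
    multiscale_extract,
    self_attention,
    spatial_attention,
    transition,
)
from btc.nn.autograd import Tensor


def loop_conv2d(x_hwc, weight, bias, pad):
    """Scalar-loop cross-correlation oracle; x is H x W x Cin, weight is
    (Cout, Cin, kh, kw)."""
    h, w, _ = x_hwc.shape
    cout, cin, kh, kw = weight.shape
    xp = np.pad(x_hwc, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, w, cout))
    for i in range(h):
        for j in range(w):
            for o in range(cout):
                acc = bias[o]
                for c in range(cin):
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += weight[o, c, ki, kj] * xp[i + ki, j + kj, c]
                out[i, j, o] = acc
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestDenseBlock:
    @pytest.mark.parametrize("g0,g,n", [(4, 2, 3), (8, 4, 2), (3, 1, 5),
                                        (1, 7, 1)])
    def test_channel_arithmetic(self, rng, g0, g, n):
        cfg = DenseBlockConfig(stages=n, growth_rate=g, initial_channels=g0)
        out = dense_block(rng.random((4, 4, g0)), cfg, seed=1)
        assert out.shape == (4, 4, g0 + n * g)

    def test_zero_stages_identity(self, rng):
        cfg = DenseBlockConfig(stages=0, growth_rate=2, initial_channels=3)
        x = rng.random((5, 5, 3))
        assert np.array_equal(dense_block(x, cfg, seed=0), x)

    def test_zero_weights_append_zero_channels(self, rng):
        cfg = DenseBlockConfig(stages=2, growth_rate=2, initial_channels=3)
        module = DenseBlock(cfg, np.random.default_rng(0))
        for stage in module.stages:
            stage.weight.data[:] = 0.0
            stage.bias.data[:] = 0.0
        x = rng.random((4, 4, 3))
        out = dense_block(x, cfg, module=module)
        assert np.array_equal(out[:, :, :3], x)
        assert np.all(out[:, :, 3:] == 0.0)

    def test_matches_loop_oracle(self, rng):
        cfg = DenseBlockConfig(stages=2, growth_rate=2, initial_channels=3)
        module = DenseBlock(cfg, np.random.default_rng(7))
        x = rng.random((4, 4, 3))
        out = dense_block(x, cfg, module=module)

        feats = x.copy()
        for stage in module.stages:
            new = loop_conv2d(feats, stage.weight.data, stage.bias.data, 1)
            new = np.maximum(new, 0.0)
            feats = np.concatenate([feats, new], axis=2)
        assert np.allclose(out, feats, atol=1e-6)

    def test_wrong_input_channels_rejected(self, rng):
        cfg = DenseBlockConfig(stages=1, growth_rate=2, initial_channels=3)
        with pytest.raises(ValueError):
            dense_block(rng.random((4, 4, 5)), cfg)


class TestTransition:
    def test_shape_halves(self, rng):
        out = transition(rng.random((8, 8, 3)), seed=0)
        assert out.shape == (4, 4, 3)

    def test_constant_preserved_with_identity_weights(self):
        module = Transition(2, 2, np.random.default_rng(0))
        module.conv.weight.data = np.eye(2)[:, :, None, None]
        module.conv.bias.data[:] = 0.0
        x = np.full((4, 4, 2), 0.7)
        assert np.allclose(transition(x, module=module), 0.7, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        module = Transition(2, 3, np.random.default_rng(4))
        x = rng.random((4, 4, 2))
        out = transition(x, module=module)
        conv = loop_conv2d(x, module.conv.weight.data, module.conv.bias.data, 0)
        pooled = np.zeros((2, 2, 3))
        for i in range(2):
            for j in range(2):
                pooled[i, j] = conv[2 * i : 2 * i + 2,
                                    2 * j : 2 * j + 2].mean(axis=(0, 1))
        assert np.allclose(out, pooled, atol=1e-6)

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            transition(rng.random((5, 6, 2)))


class TestMultiscale:
    def test_concat_width(self, rng):
        out = multiscale_extract(rng.random((6, 6, 3)),
                                 branch_widths=(4, 4, 4, 4), seed=0)
        assert out.shape == (6, 6, 16)

    def test_zero_weights_zero_output(self, rng):
        module = MultiScaleBlock(2, (2, 2, 2, 2), np.random.default_rng(0))
        for m in module.modules():
            if hasattr(m, "weight"):
                m.weight.data[:] = 0.0
                m.bias.data[:] = 0.0
        out = multiscale_extract(rng.random((4, 4, 2)), module=module)
        assert np.all(out == 0.0)

    def test_matches_loop_oracle(self, rng):
        module = MultiScaleBlock(3, (2, 3, 2, 2), np.random.default_rng(9))
        x = rng.random((6, 6, 3))
        out = multiscale_extract(x, module=module)

        relu = lambda v: np.maximum(v, 0.0)  # noqa: E731
        y1 = relu(loop_conv2d(x, module.b1.weight.data, module.b1.bias.data, 0))
        h2 = relu(loop_conv2d(x, module.b2a.weight.data, module.b2a.bias.data, 0))
        y2 = relu(loop_conv2d(h2, module.b2b.weight.data, module.b2b.bias.data, 1))
        h3 = relu(loop_conv2d(x, module.b3a.weight.data, module.b3a.bias.data, 0))
        y3 = relu(loop_conv2d(h3, module.b3b.weight.data, module.b3b.bias.data, 2))
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        pooled = np.zeros_like(x)
        for i in range(6):
            for j in range(6):
                pooled[i, j] = xp[i : i + 3, j : j + 3].max(axis=(0, 1))
        y4 = relu(loop_conv2d(pooled, module.b4.weight.data,
                              module.b4.bias.data, 0))
        assert np.allclose(out, np.concatenate([y1, y2, y3, y4], axis=2),
                           atol=1e-6)


class TestSelfAttention:
    def test_single_position_softmax_is_one(self, rng):
        """With one spatial position the attention weight is exactly 1,
        so the output is the projected value vector."""
        cfg = AttentionConfig(heads=2)
        module = SelfAttentionBlock(4, cfg, np.random.default_rng(3))
        x = rng.random((1, 1, 4))
        out = self_attention(x, cfg, module=module)
        F = x.reshape(1, 4)
        vs = [F @ module.wv[i].data + module.ev[i].data for i in range(2)]
        expected = np.concatenate(vs, axis=1) @ module.wo.data + module.bo.data
        assert np.allclose(out.reshape(1, 4), expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        cfg = AttentionConfig(heads=2)
        module = SelfAttentionBlock(6, cfg, np.random.default_rng(1))
        F = rng.normal(0, 2, (9, 6))
        for head in range(2):
            rows = module.attention_rows(F, head)
            assert np.allclose(rows.sum(axis=-1), 1.0, atol=1e-9)
            assert (rows > 0).all()

    def test_logit_shift_invariance(self, rng):
        cfg = AttentionConfig(heads=1, key_dim=3, value_dim=3)
        module = SelfAttentionBlock(3, cfg, np.random.default_rng(2))
        F = rng.normal(0, 1, (4, 3))
        rows = module.attention_rows(F, 0)
        # adding a constant to all logits of a row leaves softmax fixed
        q = F @ module.wq[0].data + module.eq[0].data
        k = F @ module.wk[0].data + module.ek[0].data
        logits = q @ k.T / module.ck + 7.5
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        assert np.allclose(rows, e / e.sum(axis=-1, keepdims=True), atol=1e-12)

    @pytest.mark.parametrize("scale_rule", ["divide_by_Ck",
                                            "divide_by_sqrt_Ck"])
    def test_matches_scalar_oracle(self, rng, scale_rule):
        cfg = AttentionConfig(heads=2, scale_rule=scale_rule)
        module = SelfAttentionBlock(4, cfg, np.random.default_rng(11))
        x = rng.normal(0, 1, (2, 2, 4))
        out = self_attention(x, cfg, module=module)

        F = x.reshape(4, 4)  # Y=4 positions, D=4
        s = module.ck if scale_rule == "divide_by_Ck" else np.sqrt(module.ck)
        heads = []
        for i in range(2):
            q = F @ module.wq[i].data + module.eq[i].data
            k = F @ module.wk[i].data + module.ek[i].data
            v = F @ module.wv[i].data + module.ev[i].data
            head = np.zeros_like(v)
            for y in range(4):
                logits = np.array([np.dot(q[y], k[z]) / s for z in range(4)])
                e = np.exp(logits - logits.max())
                attn = e / e.sum()
                for z in range(4):
                    head[y] += attn[z] * v[z]
            heads.append(head)
        expected = np.concatenate(heads, axis=1) @ module.wo.data + module.bo.data
        assert np.allclose(out.reshape(4, 4), expected, atol=1e-6)

    def test_incompatible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SelfAttentionBlock(5, AttentionConfig(heads=2),
                               np.random.default_rng(0))


class TestSpatialAttention:
    def test_gate_in_unit_interval(self, rng):
        module = SpatialAttentionBlock(np.random.default_rng(0))
        x = Tensor(rng.normal(0, 3, (1, 4, 3, 3)))
        gate = module.attention_map(x).data
        assert np.all((gate > 0) & (gate < 1))

    def test_zero_conv_gives_half_gate(self, rng):
        module = SpatialAttentionBlock(np.random.default_rng(0))
        module.conv.weight.data[:] = 0.0
        module.conv.bias.data[:] = 0.0
        x = rng.random((3, 3, 4))
        out = spatial_attention(x, module=module)
        assert np.allclose(out, x / 2.0, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        module = SpatialAttentionBlock(np.random.default_rng(5))
        x = rng.normal(0, 1, (3, 3, 4))
        out = spatial_attention(x, module=module)

        w = module.conv.weight.data  # (1, 2, 1, 1)
        b = module.conv.bias.data
        expected = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                cap = x[i, j].mean()
                cmp_ = x[i, j].max()
                f1, f2 = max(cap, 0.0), max(cmp_, 0.0)  # ReLU on concat
                gate = sigmoid(w[0, 0, 0, 0] * f1 + w[0, 1, 0, 0] * f2 + b[0])
                expected[i, j] = gate * x[i, j]
        assert np.allclose(out, expected, atol=1e-6)


class TestAggregation:
    def test_additive_identity(self, rng):
        a = rng.random((3, 3, 4))
        assert np.array_equal(aggregate_attention(a, np.zeros_like(a)), a)

    def test_commutative(self, rng):
        a, b = rng.random((3, 3, 2)), rng.random((3, 3, 2))
        assert np.array_equal(aggregate_attention(a, b),
                              aggregate_attention(b, a))

    def test_ones_plus_twos(self):
        out = aggregate_attention(np.ones((2, 2, 2)), np.full((2, 2, 2), 2.0))
        assert np.all(out == 3.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate_attention(rng.random((2, 2, 2)), rng.random((2, 2, 3)))


class TestChannelAttention:
    def test_weights_in_unit_interval(self, rng):
        module = ChannelAttentionBlock(8, 8, np.random.default_rng(0))
        weights = module.channel_weights(Tensor(rng.normal(0, 2, (1, 8, 2, 2))))
        assert np.all((weights.data > 0) & (weights.data < 1))

    def test_bottleneck_width_c_over_8(self):
        assert ChannelAttentionBlock(8, 8, np.random.default_rng(0)).c_hat == 1
        assert ChannelAttentionBlock(16, 8, np.random.default_rng(0)).c_hat == 2
        assert ChannelAttentionBlock(12, 8, np.random.default_rng(0)).c_hat == 2
        assert ChannelAttentionBlock(3, 8, np.random.default_rng(0)).c_hat == 1

    def test_matches_scalar_oracle(self, rng):
        module = ChannelAttentionBlock(16, 8, np.random.default_rng(6))
        x = rng.normal(0, 1, (2, 2, 16))
        out = channel_attention(x, module=module)

        pooled = np.array([x[:, :, c].max() for c in range(16)])  # GMP
        hidden = np.maximum(pooled @ module.fc1.weight.data
                            + module.fc1.bias.data, 0.0)
        gates = sigmoid(hidden @ module.fc2.weight.data + module.fc2.bias.data)
        expected = x * gates[None, None, :]
        assert np.allclose(out, expected, atol=1e-6)


class TestExtractor:
    def test_vector_length_and_determinism(self, rng):
        cfg = FeatureNetConfig(seed=3)
        extractor = FeatureExtractor(cfg)
        roi = rng.random((64, 64))
        v1 = extract_feature_vector(roi, extractor)
        v2 = extract_feature_vector(roi, extractor)
        assert v1.shape == (extractor.out_channels,)
        assert np.array_equal(v1, v2)

    def test_statelessness_under_permutation(self, rng):
        from btc.features import extract_features
        from btc.phantom import LabeledImage

        extractor = FeatureExtractor(FeatureNetConfig(seed=3))
        rois = [LabeledImage(pixels=rng.random((64, 64)), label="glioma")
                for _ in range(4)]
        mat = extract_features(rois, extractor)
        mat_rev = extract_features(rois[::-1], extractor)
        assert np.allclose(mat, mat_rev[::-1], atol=1e-6)

    def test_gating_blocks_preserve_sign_and_shape(self, rng):
        """Spatial/channel/SE gates only rescale by factors in (0, 1):
        signs never flip and shapes never change."""
        x = Tensor(rng.normal(0, 1, (1, 8, 4, 4)))
        spatial = SpatialAttentionBlock(np.random.default_rng(0))
        chan = ChannelAttentionBlock(8, 8, np.random.default_rng(0))
        for block in (spatial, chan):
            out = block(x)
            assert out.shape == x.shape
            assert np.all(np.sign(out.data) * np.sign(x.data) >= 0)
            assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)
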