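"""Architecture-level tests: block semantics, residual identities,
attention ranges and parameter accounting."""

import numpy as np
import pytest

from crispr_mfh import nn
from crispr_mfh.exceptions import ConfigurationError, DimensionError
from crispr_mfh.model_arch import (CSAMBlock, ChannelAttention, CrisprMFH,
                                   DTBlock, GDPBlock, ModelConfig,
                                   SpatialAttention, build_model,
                                   count_parameters, pad_to_grid)
from crispr_mfh.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(3)


@pytest.fixture
def small_config():
    return ModelConfig(dt_filters=4, attention_reduction=4,
                       mlp_sizes=(8, 4, 2), input_length=23)


class TestModelConfig:
    def test_default_invariants_hold(self):
        config = ModelConfig()
        assert config.trunk_channels % len(config.gdp_kernels) == 0

    def test_rejects_indivisible_filters(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(dt_filters=5)  # 15 % 4 != 0

    def test_rejects_bad_dropout(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(dropout=1.0)

    def test_rejects_non_binary_head(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(mlp_sizes=(80, 20, 3))

    def test_embedding_mode_is_reserved(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(encoding_mode="embedding")

    def test_round_trips_through_dict(self):
        config = ModelConfig(dt_filters=8)
        assert ModelConfig.from_dict(config.to_dict()) == config


class TestPadToGrid:
    def test_width_5_padded_to_7(self, rng):
        out = pad_to_grid(rng.random((2, 23, 5)))
        assert out.shape == (2, 23, 7)
        assert (out[:, :, 5:] == 0).all()

    def test_width_above_7_rejected(self, rng):
        with pytest.raises(DimensionError):
            pad_to_grid(rng.random((2, 23, 8)))


class TestDTBlock:
    def test_zero_input_zero_bias_gives_zeros(self, small_config, rng):
        block = DTBlock(small_config, rng)
        block.conv.bias.data[:] = 0.0
        out = block(np.zeros((2, 23, 5), dtype=np.float32))
        assert np.all(out.data == 0.0)

    def test_output_shape_is_l_by_7_by_f(self, small_config, rng):
        block = DTBlock(small_config, rng)
        assert block(rng.random((3, 23, 7))).shape == (3, 23, 7, 4)

    def test_identity_kernel_inference_bn_is_relu(self, rng):
        # 1x1 identity-like kernel, inference BN with unit statistics:
        # the block must reduce to ReLU(input) in its first channel
        config = ModelConfig(dt_filters=4, dt_kernel=1,
                             attention_reduction=4, mlp_sizes=(8, 4, 2))
        block = DTBlock(config, rng)
        block.conv.weight.data[:] = 0.0
        block.conv.weight.data[0, 0, 0, 0] = 1.0
        block.conv.bias.data[:] = 0.0
        x = rng.normal(size=(2, 23, 7)).astype(np.float32)
        out = block(x, training=False)
        # inference BN with unit running stats rescales by 1/sqrt(1 + eps)
        np.testing.assert_allclose(out.data[..., 0], np.maximum(x, 0.0),
                                   rtol=1e-4, atol=1e-6)


class TestGDPBlock:
    def test_zero_weights_residual_identity(self, rng):
        block = GDPBlock(8, (1, 3, 5, 7), rng)
        for pointwise in block.pointwise:
            pointwise.weight.data[:] = 0.0
            pointwise.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 23, 7, 8)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_output_shape_preserved(self, rng):
        block = GDPBlock(12, (1, 3, 5, 7), rng)
        x = Tensor(rng.normal(size=(2, 23, 7, 12)).astype(np.float32))
        assert block(x).shape == x.shape

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            GDPBlock(6, (1, 3, 5, 7), rng)

    def test_single_branch_1x1_matches_matmul_oracle(self, rng):
        # one depthwise 1x1 + pointwise 1x1 branch == two known matmuls
        block = GDPBlock(4, (1,), rng)
        x = rng.normal(size=(1, 3, 3, 4)).astype(np.float32)
        dw = block.depthwise[0].weight.data[0, 0]  # (4,)
        pw = block.pointwise[0].weight.data[0, 0]  # 4 x 4
        pb = block.pointwise[0].bias.data
        expected = x + ((x * dw).reshape(-1, 4) @ pw + pb).reshape(x.shape)
        np.testing.assert_allclose(block(Tensor(x)).data, expected, rtol=2e-4,
                                   atol=1e-5)


class TestChannelAttention:
    def test_zero_input_zero_bias_gives_half(self, rng):
        attention = ChannelAttention(8, 4, rng)
        attention.fc1.bias.data[:] = 0.0
        attention.fc2.bias.data[:] = 0.0
        weights = attention(Tensor(np.zeros((2, 5, 3, 8), dtype=np.float32)))
        np.testing.assert_allclose(weights.data, 0.5, atol=1e-6)

    def test_spatially_constant_input_doubles_mlp(self, rng):
        attention = ChannelAttention(8, 4, rng)
        constant = rng.normal(size=(1, 1, 1, 8)).astype(np.float32)
        x = Tensor(np.broadcast_to(constant, (1, 5, 3, 8)).copy())
        descriptor = Tensor(constant.reshape(1, 8))
        mlp_out = attention._mlp(descriptor)
        expected = 1.0 / (1.0 + np.exp(-2.0 * mlp_out.data))
        np.testing.assert_allclose(attention(x).data.reshape(1, 8), expected,
                                   rtol=1e-5)

    def test_hand_computed_two_channel_case(self):
        rng = np.random.default_rng(0)
        attention = ChannelAttention(2, 2, rng)
        attention.fc1.weight.data = np.array([[1.0], [1.0]], dtype=np.float32)
        attention.fc1.bias.data = np.zeros(1, dtype=np.float32)
        attention.fc2.weight.data = np.array([[1.0, -1.0]], dtype=np.float32)
        attention.fc2.bias.data = np.zeros(2, dtype=np.float32)
        x = np.zeros((1, 2, 2, 2), dtype=np.float32)
        x[0, :, :, 0] = [[1, 2], [3, 4]]  # GAP 2.5, GMP 4
        x[0, :, :, 1] = 1.0               # GAP 1, GMP 1
        # descriptors: gap=[2.5,1], gmp=[4,1]; fc1: relu(3.5)=3.5, relu(5)=5
        # fc2 rows: [h,-h] -> sum=[8.5,-8.5]; sigmoid
        expected = 1.0 / (1.0 + np.exp(-np.array([8.5, -8.5])))
        np.testing.assert_allclose(attention(Tensor(x)).data.reshape(2),
                                   expected, rtol=1e-5)

    def test_channels_below_reduction_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ChannelAttention(4, 8, rng)

    def test_weights_strictly_inside_unit_interval(self, rng):
        attention = ChannelAttention(8, 4, rng)
        weights = attention(Tensor(rng.normal(size=(3, 5, 3, 8)) * 5)).data
        assert np.all(weights > 0.0) and np.all(weights < 1.0)


class TestSpatialAttention:
    def test_zero_conv_gives_half_everywhere(self, rng):
        attention = SpatialAttention(rng)
        attention.conv.weight.data[:] = 0.0
        attention.conv.bias.data[:] = 0.0
        out = attention(Tensor(rng.normal(size=(2, 23, 7, 8)).astype(np.float32)))
        assert out.shape == (2, 23, 7, 1)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-6)

    def test_matches_brute_force_convolution_oracle(self, rng):
        attention = SpatialAttention(rng)
        x = rng.normal(size=(1, 4, 4, 1)).astype(np.float32)
        kernel = attention.conv.weight.data  # 7 x 7 x 2 x 1
        bias = float(attention.conv.bias.data[0])
        # single channel: mean map == max map == x
        stacked = np.concatenate([x, x], axis=3)
        padded = np.pad(stacked, ((0, 0), (3, 3), (3, 3), (0, 0)))
        out = attention(Tensor(x)).data
        for h in range(4):
            for w in range(4):
                acc = bias
                for i in range(7):
                    for j in range(7):
                        for c in range(2):
                            acc += padded[0, h + i, w + j, c] * kernel[i, j, c, 0]
                assert out[0, h, w, 0] == pytest.approx(
                    1 / (1 + np.exp(-acc)), rel=1e-3)


class TestCSAMBlock:
    def test_zero_fusion_weights_residual_identity(self, rng):
        block = CSAMBlock(8, 4, rng)
        block.fuse.weight.data[:] = 0.0
        block.fuse.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 23, 7, 8)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_matches_composition_of_attention_oracles(self, rng):
        block = CSAMBlock(8, 4, rng)
        x = Tensor(rng.normal(size=(1, 5, 7, 8)).astype(np.float32))
        ca = block.channel_attention(x).data
        sa = block.spatial_attention(x).data
        stacked = np.concatenate([ca * x.data, sa * x.data], axis=3)
        fused = (stacked.reshape(-1, 16) @ block.fuse.weight.data[0, 0]
                 + block.fuse.bias.data).reshape(x.data.shape)
        np.testing.assert_allclose(block(x).data, x.data + fused, rtol=2e-4,
                                   atol=1e-5)


class TestFullModel:
    def test_forward_softmax_sums_to_one(self, small_config, rng):
        model = CrisprMFH(small_config, seed=0)
        sg = rng.integers(0, 2, size=(1, 23, 5)).astype(np.float32)
        dn = rng.integers(0, 2, size=(1, 23, 5)).astype(np.float32)
        fu = rng.integers(0, 2, size=(1, 23, 7)).astype(np.float32)
        probs = model.predict_proba(sg, dn, fu)
        assert probs.shape == (1, 2)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_batch_output_shape(self, small_config, rng):
        model = CrisprMFH(small_config, seed=0)
        n = 5
        probs = model.predict_proba(
            rng.random((n, 23, 5)).astype(np.float32),
            rng.random((n, 23, 5)).astype(np.float32),
            rng.random((n, 23, 7)).astype(np.float32))
        assert probs.shape == (n, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, small_config, rng):
        model = CrisprMFH(small_config, seed=0)
        inputs = [rng.random((3, 23, 5)).astype(np.float32),
                  rng.random((3, 23, 5)).astype(np.float32),
                  rng.random((3, 23, 7)).astype(np.float32)]
        first = model.predict_proba(*inputs)
        second = model.predict_proba(*inputs)
        np.testing.assert_array_equal(first, second)

    def test_checkpoint_round_trip(self, small_config, rng, tmp_path):
        model = CrisprMFH(small_config, seed=1)
        inputs = [rng.random((2, 23, 5)).astype(np.float32),
                  rng.random((2, 23, 5)).astype(np.float32),
                  rng.random((2, 23, 7)).astype(np.float32)]
        before = model.predict_proba(*inputs)
        path = model.save(tmp_path / "model.npz")
        restored = CrisprMFH.load(path)
        np.testing.assert_array_equal(restored.predict_proba(*inputs), before)


def shape_walk_parameter_count(config: ModelConfig) -> int:
    """Independent closed-form parameter arithmetic for the default graph."""
    k, f = config.dt_kernel, config.dt_filters
    total = 3 * (k * k * 1 * f + f + 2 * f)  # DT conv + bias + BN gamma/beta
    channels = config.trunk_channels
    branch_out = channels // len(config.gdp_kernels)
    total += sum(ki * ki * channels for ki in config.gdp_kernels)  # depthwise
    total += len(config.gdp_kernels) * (channels * branch_out + branch_out)
    hidden = max(1, channels // config.attention_reduction)  # channel attn MLP
    total += channels * hidden + hidden + hidden * channels + channels
    total += 7 * 7 * 2 * 1 + 1  # spatial attention conv
    total += (2 * channels) * channels + channels  # 1x1 fusion
    flat = config.input_length * 7 * channels
    sizes = (flat,) + tuple(config.mlp_sizes)
    total += sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
    return total


class TestParameterCount:
    def test_dense_layer_arithmetic(self, rng):
        assert sum(p.data.size for p in nn.Dense(80, 20, rng).parameters()) == 1620
        assert sum(p.data.size for p in nn.Dense(20, 2, rng).parameters()) == 42

    @pytest.mark.parametrize("config", [
        ModelConfig(),
        ModelConfig(dt_filters=8),
        ModelConfig(dt_filters=4, attention_reduction=4, mlp_sizes=(8, 4, 2)),
    ])
    def test_matches_shape_walking_oracle(self, config):
        model, report = build_model(config)
        assert count_parameters(model) == shape_walk_parameter_count(config)
        assert report["total_parameters"] == count_parameters(model)
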