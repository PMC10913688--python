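"""Every network block against an independent loop-based reference."""

import numpy as np
import pytest

import oracles
from promoter5mc.autodiff import Tensor
from promoter5mc.nn import (
    BiGRU, CBAM, ChannelAttention, ClassifierHead, DenseBlock, DenseLayer,
    GRUCell, SelfAttention, SpatialAttention, Transition, gru_step,
)

SEEDS = list(range(20))


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestChannelAttention:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 6))
        mod = ChannelAttention(c, reduction=2, rng=rng)
        x = rng.standard_normal((2, c, 3, 4))
        w, y = mod(Tensor(x), return_weights=True)
        ow, oy = oracles.channel_attention(
            x, mod.fc1.weight.data, mod.fc1.bias.data,
            mod.fc2.weight.data, mod.fc2.bias.data)
        np.testing.assert_allclose(w.data, ow, atol=1e-6)
        np.testing.assert_allclose(y.data, oy, atol=1e-6)
        assert np.all((w.data > 0) & (w.data < 1))

    def test_zero_parameters_halve_input(self, rng):
        mod = ChannelAttention(4, reduction=2, rng=rng)
        _zero_params(mod)
        x = rng.standard_normal((3, 4, 2, 2))
        w, y = mod(Tensor(x), return_weights=True)
        np.testing.assert_allclose(w.data, 0.5)
        np.testing.assert_allclose(y.data, 0.5 * x)

    def test_shape_preserved(self, rng):
        mod = ChannelAttention(5, reduction=8, rng=rng)  # reduction clamps to >=1
        x = rng.standard_normal((2, 5, 4, 7))
        assert mod(Tensor(x)).shape == x.shape


class TestSpatialAttention:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        kernel = int(rng.choice([3, 5, 7]))
        mod = SpatialAttention(kernel, rng)
        x = rng.standard_normal((2, 3, 4, 5))
        w, y = mod(Tensor(x), return_weights=True)
        ow, oy = oracles.spatial_attention(
            x, mod.conv.weight.data, mod.conv.bias.data, kernel)
        np.testing.assert_allclose(w.data, ow, atol=1e-6)
        np.testing.assert_allclose(y.data, oy, atol=1e-6)

    def test_zero_parameters_halve_input(self, rng):
        mod = SpatialAttention(3, rng)
        _zero_params(mod)
        x = rng.standard_normal((2, 3, 4, 5))
        w, y = mod(Tensor(x), return_weights=True)
        np.testing.assert_allclose(w.data, 0.5)
        np.testing.assert_allclose(y.data, 0.5 * x)

    def test_constant_input_gives_constant_interior_weights(self, rng):
        # translation symmetry away from padding effects
        mod = SpatialAttention(3, rng)
        x = np.full((1, 4, 6, 9), 1.7)
        w, _ = mod(Tensor(x), return_weights=True)
        interior = w.data[0, 0, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, interior[0, 0], atol=1e-12)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            SpatialAttention(4, rng)


class TestCbam:
    def test_order_is_channel_then_spatial(self, rng):
        mod = CBAM(4, reduction=2, kernel=3, rng=rng)
        x = Tensor(rng.standard_normal((2, 4, 3, 5)))
        expected = mod.spatial(mod.channel(x))
        np.testing.assert_array_equal(mod(x).data, expected.data)
        reversed_order = mod.channel(mod.spatial(x))
        assert not np.allclose(mod(x).data, reversed_order.data)

    def test_zero_parameterised_quarters_input(self, rng):
        mod = CBAM(3, reduction=1, kernel=3, rng=rng)
        _zero_params(mod)
        x = rng.standard_normal((2, 3, 4, 4))
        np.testing.assert_allclose(mod(Tensor(x)).data, 0.25 * x, atol=1e-12)

    @pytest.mark.parametrize("shape", [(1, 2, 3, 4), (3, 7, 7, 41), (2, 5, 1, 6)])
    def test_shape_preserved(self, rng, shape):
        mod = CBAM(shape[1], reduction=2, kernel=3, rng=rng)
        assert mod(Tensor(rng.standard_normal(shape))).shape == shape


class TestDenseLayer:
    @pytest.mark.parametrize("seed", SEEDS[:10])
    def test_matches_stage_composed_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        c_in, growth = 7, 5
        layer = DenseLayer(c_in, growth, reduction=2, spatial_kernel=3, rng=rng)
        layer.eval()  # frozen batch statistics
        x = rng.standard_normal((2, c_in, 7, 11))
        got = layer(Tensor(x)).data
        bn = oracles.batchnorm_eval(x, layer.bn.gamma.data, layer.bn.beta.data,
                                    layer.bn.running_mean, layer.bn.running_var)
        act = np.maximum(bn, 0.0)
        conv = oracles.conv2d(act, layer.conv.weight.data, layer.conv.bias.data, (1, 1))
        _, after_ch = oracles.channel_attention(
            conv, layer.cbam.channel.fc1.weight.data, layer.cbam.channel.fc1.bias.data,
            layer.cbam.channel.fc2.weight.data, layer.cbam.channel.fc2.bias.data)
        _, expected = oracles.spatial_attention(
            after_ch, layer.cbam.spatial.conv.weight.data,
            layer.cbam.spatial.conv.bias.data, 3)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_output_channels_equal_growth_rate(self, rng):
        for c_in in (1, 4, 9):
            layer = DenseLayer(c_in, 6, reduction=2, spatial_kernel=3, rng=rng)
            layer.eval()
            out = layer(Tensor(rng.standard_normal((2, c_in, 5, 8))))
            assert out.shape == (2, 6, 5, 8)  # H, W unchanged by same padding


class TestDenseBlock:
    def test_channel_count(self, rng):
        block = DenseBlock(7, num_layers=4, growth_rate=12, reduction=2,
                           spatial_kernel=3, rng=rng)
        block.eval()
        out = block(Tensor(rng.standard_normal((1, 7, 4, 6))))
        assert out.shape == (1, 7 + 4 * 12, 4, 6)

    def test_input_passes_through_unchanged(self, rng):
        block = DenseBlock(3, num_layers=2, growth_rate=4, reduction=2,
                           spatial_kernel=3, rng=rng)
        block.eval()
        x = rng.standard_normal((2, 3, 4, 5))
        out = block(Tensor(x)).data
        np.testing.assert_array_equal(out[:, :3], x)

    def test_first_layer_sees_block_input(self, rng):
        block = DenseBlock(3, num_layers=2, growth_rate=4, reduction=2,
                           spatial_kernel=3, rng=rng)
        block.eval()
        x = Tensor(rng.standard_normal((1, 3, 4, 5)))
        first = block.layer0(x)
        np.testing.assert_array_equal(block(x).data[:, 3:7], first.data)


class TestTransition:
    def test_channel_compression(self, rng):
        t = Transition(56, 0.5, rng)
        t.eval()
        out = t(Tensor(rng.standard_normal((1, 56, 6, 10))))
        assert out.shape == (1, 28, 3, 5)

    def test_ceiling_mode_spatial(self, rng):
        t = Transition(8, 0.5, rng)
        t.eval()
        out = t(Tensor(rng.standard_normal((1, 8, 7, 41))))
        assert out.shape[2:] == (4, 21)

    def test_odd_compression_rounds_up(self, rng):
        assert Transition(7, 0.5, rng).c_out == 4


class TestGru:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_step_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        cell = GRUCell(3, 3, rng)
        x_t = rng.standard_normal(3)
        h_prev = rng.standard_normal(3)
        got = gru_step(cell, x_t[None], h_prev[None]).data[0]
        params = {name: getattr(cell, name).data
                  for name in ("W_r", "U_r", "b_r", "W_z", "U_z", "b_z", "W_h", "U_h", "b_h")}
        np.testing.assert_allclose(got, oracles.gru_step(x_t, h_prev, params), atol=1e-10)

    def test_zero_weights_halve_state(self, rng):
        cell = GRUCell(2, 4, rng)
        _zero_params(cell)
        h_prev = rng.standard_normal((1, 4))
        out = gru_step(cell, np.zeros((1, 2)), h_prev)
        np.testing.assert_allclose(out.data, 0.5 * h_prev)

    def test_zero_state_zero_input_fixed_point(self, rng):
        cell = GRUCell(3, 5, rng)  # random weights, zero biases
        out = gru_step(cell, np.zeros((2, 3)), np.zeros((2, 5)))
        np.testing.assert_allclose(out.data, 0.0)


class TestBiGru:
    def test_output_dimension(self, rng):
        gru = BiGRU(4, 6, rng)
        out = gru(Tensor(rng.standard_normal((3, 5, 4))))
        assert out.shape == (3, 5, 12)

    def test_palindrome_with_tied_directions(self, rng):
        gru = BiGRU(3, 4, rng)
        # tie backward parameters to forward ones
        for name in ("W_r", "U_r", "b_r", "W_z", "U_z", "b_z", "W_h", "U_h", "b_h"):
            getattr(gru.bwd, name).data = getattr(gru.fwd, name).data.copy()
        row = rng.standard_normal((1, 1, 3))
        x = np.concatenate([row, row * 2.0, row], axis=1)  # palindromic length 3
        out = gru(Tensor(x)).data[0]
        fwd, bwd = out[:, :4], out[:, 4:]
        np.testing.assert_allclose(fwd, bwd[::-1], atol=1e-12)

    def test_length_one_directions_agree(self, rng):
        gru = BiGRU(3, 4, rng)
        for name in ("W_r", "U_r", "b_r", "W_z", "U_z", "b_z", "W_h", "U_h", "b_h"):
            getattr(gru.bwd, name).data = getattr(gru.fwd, name).data.copy()
        out = gru(Tensor(rng.standard_normal((2, 1, 3)))).data
        np.testing.assert_allclose(out[:, 0, :4], out[:, 0, 4:])


class TestSelfAttention:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        mod = SelfAttention(4, 4, rng)
        x = rng.standard_normal((1, 3, 4))
        ctx, attn = mod(Tensor(x), return_attn=True)
        octx, oattn = oracles.self_attention(
            x[0], mod.q.weight.data, mod.q.bias.data,
            mod.k.weight.data, mod.k.bias.data,
            mod.v.weight.data, mod.v.bias.data, mod.scale)
        np.testing.assert_allclose(ctx.data[0], octx, atol=1e-8)
        np.testing.assert_allclose(attn.data[0], oattn, atol=1e-8)

    def test_rows_sum_to_one(self, rng):
        mod = SelfAttention(5, 3, rng)
        _, attn = mod(Tensor(rng.standard_normal((4, 6, 5))), return_attn=True)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all((attn.data > 0) & (attn.data < 1))

    def test_single_position_attends_to_itself(self, rng):
        mod = SelfAttention(4, 4, rng)
        x = rng.standard_normal((1, 1, 4))
        ctx, attn = mod(Tensor(x), return_attn=True)
        np.testing.assert_allclose(attn.data, 1.0)
        v = x[0] @ mod.v.weight.data + mod.v.bias.data
        np.testing.assert_allclose(ctx.data[0], v, atol=1e-12)

    def test_unscaled_variant(self, rng):
        assert SelfAttention(9, 9, rng, scale=False).scale == 1.0
        assert SelfAttention(4, 9, rng, scale=True).scale == pytest.approx(1 / 3)


class TestClassifierHead:
    @pytest.mark.parametrize("seed", SEEDS[:5])
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        head = ClassifierHead(6, rng)
        v = rng.standard_normal(6)
        got = head(Tensor(v[None])).data[0]
        np.testing.assert_allclose(
            got, oracles.softmax_head(v, head.fc.weight.data, head.fc.bias.data),
            atol=1e-10)

    def test_zero_parameters_give_uniform(self, rng):
        head = ClassifierHead(4, rng)
        _zero_params(head)
        np.testing.assert_allclose(head(Tensor(rng.standard_normal((3, 4)))).data, 0.5)

    def test_probabilities_sum_to_one(self, rng):
        head = ClassifierHead(4, rng)
        out = head(Tensor(rng.standard_normal((10, 4)))).data
        assert np.all(out > 0)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_logit_shift_invariance(self, rng):
        head = ClassifierHead(3, rng)
        v = Tensor(rng.standard_normal((2, 3)))
        base = head(v).data
        head.fc.bias.data = head.fc.bias.data + 5.0  # same constant on both logits
        np.testing.assert_allclose(head(v).data, base, atol=1e-12)
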