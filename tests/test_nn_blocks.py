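"""Layer containers, residual blocks, and parameter bookkeeping."""

import numpy as np
import pytest

from hepaseg import nn
from hepaseg.autograd import Tensor
from hepaseg.blocks import (ConvUnit, DecoderResidualBlock, DoubleConv,
                            EncoderResidualBlock, ResidualBlock, conv1_unit,
                            conv2_unit, separable_parameter_count)
from hepaseg.nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d,
                        DepthwiseSeparableConv2d, Dropout)


class TestModuleSystem:
    def test_named_parameters_and_state_roundtrip(self, rng):
        block = ResidualBlock(3, 8, rng=rng)
        names = [n for n, _ in block.named_parameters()]
        assert len(names) == len(set(names)), "duplicate parameter names"
        state = {k: v.copy() for k, v in block.state_dict().items()}
        for p in block.parameters():
            p.data = p.data + 1.0
        block.load_state_dict(state)
        for k, v in block.state_dict().items():
            np.testing.assert_array_equal(v, state[k])

    def test_train_eval_propagates(self, rng):
        block = DoubleConv(3, 4, rng=rng)
        block.eval()
        assert all(not m.training for m in block.modules())
        block.train()
        assert all(m.training for m in block.modules())


class TestLayers:
    def test_conv2d_same_shape(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 10, 10)).astype(np.float32))
        assert Conv2d(3, 5, rng=rng)(x).shape == (2, 5, 10, 10)
        assert Conv2d(3, 5, kernel=1, rng=rng)(x).shape == (2, 5, 10, 10)
        assert Conv2d(3, 5, dilation=3, rng=rng)(x).shape == (2, 5, 10, 10)

    def test_separable_conv_parameter_savings(self, rng):
        sep = DepthwiseSeparableConv2d(32, 32, kernel=3, rng=rng)
        n_sep = sum(p.data.size for p in sep.parameters())
        assert n_sep == separable_parameter_count(32, 32, 3) == 1312
        dense = Conv2d(32, 32, kernel=3, bias=False, rng=rng)
        n_dense = sum(p.data.size for p in dense.parameters())
        assert n_dense == 9216
        assert n_sep < n_dense / 7

    def test_separable_rejects_even_kernel(self, rng):
        with pytest.raises(ValueError, match="even"):
            DepthwiseSeparableConv2d(4, 4, kernel=2, rng=rng)

    def test_transposed_conv_doubles_resolution(self, rng):
        x = Tensor(rng.normal(size=(1, 8, 5, 7)).astype(np.float32))
        assert ConvTranspose2d(8, 4, rng=rng)(x).shape == (1, 4, 10, 14)

    def test_batchnorm_normalizes_in_training(self, rng):
        bn = BatchNorm2d(3)
        x = Tensor(rng.normal(2.0, 5.0, size=(4, 3, 8, 8)))
        out = bn(x).data
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = BatchNorm2d(2)
        x = Tensor(rng.normal(1.0, 2.0, size=(8, 2, 4, 4)))
        for _ in range(50):
            bn(x)
        bn.eval()
        out = bn(x).data
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=0.05)

    def test_dropout_eval_identity_and_scaling(self, rng):
        d = Dropout(0.5, rng=np.random.default_rng(0))
        x = Tensor(np.ones((1, 1, 50, 50)))
        masked = d(x).data
        assert set(np.unique(masked)) == {0.0, 2.0}
        d.eval()
        np.testing.assert_array_equal(d(x).data, x.data)
        with pytest.raises(ValueError):
            Dropout(1.0)

    def test_adam_minimizes_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = ((p - Tensor(np.array([1.0, 2.0]))) ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        np.testing.assert_allclose(p.data, [1.0, 2.0], atol=1e-3)


class TestResidualBlocks:
    def test_conv_units(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
        act = conv1_unit(3, 4, rng=rng)(x)
        assert act.shape == (2, 4, 6, 6)
        assert (act.data >= 0).all(), "conv1 unit output must pass ReLU"
        lin = conv2_unit(3, 4, rng=rng)(x)
        assert (lin.data < 0).any(), "conv2 unit must not be activated"

    def test_zeroed_branch_reduces_to_skip_path(self, rng):
        block = ResidualBlock(3, 6, rng=rng)
        block.zero_branch_()
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        full = block(x).data
        a = block.entry(x)
        skip_only = block.exit(a + 0.0 * a).data
        np.testing.assert_allclose(full, skip_only, atol=1e-6)

    def test_encoder_decoder_flavors(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        enc = EncoderResidualBlock(4, 8, rng=rng)(x)
        assert (enc.data >= 0).all(), "encoder blocks end in ReLU"
        dec = DecoderResidualBlock(4, 8, rng=rng)(x)
        assert (dec.data > -1.0).all(), "decoder ELU is bounded below by -1"
        assert (dec.data < 0).any(), "decoder ELU passes negatives"

    def test_rejects_bad_channel_counts(self, rng):
        with pytest.raises(ValueError):
            ResidualBlock(0, 4, rng=rng)
        with pytest.raises(ValueError):
            ConvUnit(4, -1, rng=rng)
        with pytest.raises(ValueError, match="unknown activation"):
            ConvUnit(2, 2, activation="swish", rng=rng)(
                Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32)))
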