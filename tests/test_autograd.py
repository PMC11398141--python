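"""Gradient and semantics checks for the reverse-mode autodiff engine."""

import numpy as np
import pytest

from hepaseg import autograd as ag
from hepaseg.autograd import Tensor, no_grad

from conftest import check_grad, naive_conv2d


class TestElementwise:
    def test_arithmetic_values(self):
        a = Tensor(np.array([1.0, -2.0, 3.0]))
        b = Tensor(np.array([4.0, 5.0, -6.0]))
        np.testing.assert_allclose((a + b).data, [5.0, 3.0, -3.0])
        np.testing.assert_allclose((a * b).data, [4.0, -10.0, -18.0])
        np.testing.assert_allclose((a / b).data, [0.25, -0.4, -0.5])
        np.testing.assert_allclose((1.0 - a).data, [0.0, 3.0, -2.0])
        np.testing.assert_allclose((a ** 2).data, [1.0, 4.0, 9.0])

    def test_scalar_ops_preserve_float32(self):
        a = Tensor(np.ones(4, dtype=np.float32))
        for t in (a + 1.0, a * 2.0, a / 3.0, 1.0 - a, 2.0 * a, -a):
            assert t.data.dtype == np.float32

    def test_relu_elu_sigmoid_values(self):
        x = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
        np.testing.assert_allclose(ag.relu(Tensor(x)).data,
                                   np.maximum(x, 0.0))
        expected_elu = np.where(x > 0, x, np.expm1(x))
        np.testing.assert_allclose(ag.elu(Tensor(x)).data, expected_elu,
                                   rtol=1e-12)
        np.testing.assert_allclose(ag.sigmoid(Tensor(x)).data,
                                   1.0 / (1.0 + np.exp(-x)), rtol=1e-12)

    def test_elementwise_gradients(self, rng):
        x = rng.normal(size=(3, 4))
        y = rng.normal(size=(3, 4)) + 3.0
        check_grad(lambda t: ag.tsum(t["x"] * t["y"] + t["x"] / t["y"]),
                   {"x": x, "y": y})
        check_grad(lambda t: ag.tsum(ag.sigmoid(t["x"]) * ag.elu(t["x"])),
                   {"x": x})
        check_grad(lambda t: ag.tsum(ag.exp(t["x"]) + ag.log(t["y"])),
                   {"x": x, "y": y})
        check_grad(lambda t: ag.tsum(ag.sqrt(t["y"]) * t["x"] ** 3),
                   {"x": x, "y": y})

    def test_broadcasting_gradient(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        s = rng.normal(size=(1, 3, 1, 1))
        check_grad(lambda t: ag.tsum(t["x"] * t["s"] + t["s"]),
                   {"x": x, "s": s})


class TestReductionsAndShapes:
    def test_sum_mean_max(self, rng):
        x = rng.normal(size=(2, 3, 5))
        np.testing.assert_allclose(ag.tsum(Tensor(x), axis=1).data,
                                   x.sum(axis=1))
        np.testing.assert_allclose(
            ag.tmean(Tensor(x), axis=(1, 2), keepdims=True).data,
            x.mean(axis=(1, 2), keepdims=True))
        np.testing.assert_allclose(ag.tmax(Tensor(x), axis=2).data,
                                   x.max(axis=2))

    def test_reduction_gradients(self, rng):
        x = rng.normal(size=(3, 4, 5))
        check_grad(lambda t: ag.tsum(ag.tmean(t["x"], axis=1) ** 2), {"x": x})
        check_grad(lambda t: ag.tsum(
            ag.tmax(t["x"], axis=2, keepdims=True) * 2.0), {"x": x})

    def test_reshape_concat_broadcast_hw(self, rng):
        x = rng.normal(size=(2, 3, 2, 2))
        y = rng.normal(size=(2, 1, 2, 2))
        cat = ag.concat([Tensor(x), Tensor(y)], axis=1)
        assert cat.shape == (2, 4, 2, 2)
        bc = ag.broadcast_hw(Tensor(rng.normal(size=(2, 3, 1, 1))), 5, 7)
        assert bc.shape == (2, 3, 5, 7)
        check_grad(lambda t: ag.tsum(
            ag.concat([t["x"], t["y"]], axis=1) ** 2), {"x": x, "y": y})
        check_grad(lambda t: ag.tsum(
            ag.broadcast_hw(t["p"], 4, 4) * ag.reshape(t["q"], (2, 3, 4, 4))),
            {"p": rng.normal(size=(2, 3, 1, 1)),
             "q": rng.normal(size=(2, 48))})


class TestConvolutions:
    def test_conv2d_matches_naive(self, rng):
        x = rng.normal(size=(2, 3, 6, 7))
        w = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        got = ag.conv2d(Tensor(x), Tensor(w), Tensor(b)).data
        np.testing.assert_allclose(got, naive_conv2d(x, w, b), rtol=1e-10)

    def test_conv2d_dilated_matches_naive(self, rng):
        x = rng.normal(size=(1, 2, 9, 9))
        w = rng.normal(size=(3, 2, 3, 3))
        got = ag.conv2d(Tensor(x), Tensor(w), dilation=2).data
        np.testing.assert_allclose(got, naive_conv2d(x, w, dilation=2),
                                   rtol=1e-10)

    def test_conv2d_gradients(self, rng):
        for dilation, k in [(1, 3), (2, 3), (1, 1)]:
            x = rng.normal(size=(2, 2, 5, 5))
            w = rng.normal(size=(3, 2, k, k))
            b = rng.normal(size=3)
            check_grad(
                lambda t, d=dilation: ag.tsum(
                    ag.conv2d(t["x"], t["w"], t["b"], dilation=d) ** 2),
                {"x": x, "w": w, "b": b})

    def test_conv2d_channel_mismatch_raises(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        w = Tensor(rng.normal(size=(2, 5, 3, 3)))
        with pytest.raises(ValueError, match="channel"):
            ag.conv2d(x, w)

    def test_depthwise_conv_gradients(self, rng):
        x = rng.normal(size=(2, 3, 6, 6))
        w = rng.normal(size=(3, 3, 3))
        check_grad(lambda t: ag.tsum(
            ag.depthwise_conv2d(t["x"], t["w"], dilation=2) ** 2),
            {"x": x, "w": w})

    def test_transposed_conv_shape_and_gradients(self, rng):
        x = rng.normal(size=(2, 4, 3, 3))
        w = rng.normal(size=(4, 2, 2, 2))
        b = rng.normal(size=2)
        out = ag.conv_transpose2d_2x2(Tensor(x), Tensor(w), Tensor(b))
        assert out.shape == (2, 2, 6, 6)
        check_grad(lambda t: ag.tsum(
            ag.conv_transpose2d_2x2(t["x"], t["w"], t["b"]) ** 2),
            {"x": x, "w": w, "b": b})

    def test_maxpool_semantics_and_gradient(self, rng):
        x = np.array([[[[1.0, 2.0, 5.0, 1.0],
                        [3.0, 4.0, 2.0, 0.0],
                        [0.0, 1.0, 1.0, 1.0],
                        [2.0, 1.0, 1.0, 9.0]]]])
        out = ag.maxpool2d_2x2(Tensor(x))
        np.testing.assert_allclose(out.data, [[[[4.0, 5.0], [2.0, 9.0]]]])
        xr = rng.normal(size=(2, 3, 4, 4))
        check_grad(lambda t: ag.tsum(ag.maxpool2d_2x2(t["x"]) ** 2),
                   {"x": xr})

    def test_batchnorm_gradients(self, rng):
        x = rng.normal(size=(3, 2, 4, 4))
        gamma = rng.normal(size=(1, 2, 1, 1)) + 1.0
        beta = rng.normal(size=(1, 2, 1, 1))
        check_grad(lambda t: ag.tsum(
            ag.batchnorm2d(t["x"], t["g"], t["b"])[0] ** 3),
            {"x": x, "g": gamma, "b": beta}, rtol=5e-5, atol=1e-6)


class TestGraphMechanics:
    def test_grad_accumulates_over_reuse(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = x * x + x  # dy/dx = 2x + 1 = 5
        y.backward()
        np.testing.assert_allclose(x.grad, [5.0])

    def test_no_grad_blocks_graph(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        with no_grad():
            y = x * x
        assert y.requires_grad is False

    def test_backward_requires_scalar_or_grad(self):
        x = Tensor(np.ones((2, 2)), requires_grad=True)
        with pytest.raises(ValueError):
            (x * 2.0).backward()
        (x * 2.0).backward(np.ones((2, 2)))
        np.testing.assert_allclose(x.grad, 2.0 * np.ones((2, 2)))

    def test_deep_chain_backward(self):
        x = Tensor(np.array([1.0]), requires_grad=True)
        y = x
        for _ in range(300):
            y = y + 0.01
        ag.tsum(y).backward()
        np.testing.assert_allclose(x.grad, [1.0])
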