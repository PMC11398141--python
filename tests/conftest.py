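"""Shared test helpers: brute-force oracles and numerical gradient checks.

The oracles here are deliberately naive (explicit loops, float64) so that
they are independent of the vectorized implementations they check.
"""

import numpy as np
import pytest

from hepaseg.autograd import Tensor


def naive_conv2d(x, w, b=None, dilation=1, padding=None):
    """Direct-loop 'same' cross-correlation oracle.

    x: (B, C, H, W), w: (O, C, k, k); stride 1, zero padding chosen so the
    output matches the input spatially (odd kernels).
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    bsz, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    if padding is None:
        padding = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = np.zeros((bsz, cout, h, wd))
    for bi in range(bsz):
        for oc in range(cout):
            for i in range(h):
                for j in range(wd):
                    acc = 0.0
                    for ic in range(cin):
                        for ki in range(k):
                            for kj in range(k):
                                acc += (w[oc, ic, ki, kj]
                                        * xp[bi, ic, i + ki * dilation,
                                             j + kj * dilation])
                    out[bi, oc, i, j] = acc
            if b is not None:
                out[bi, oc] += np.asarray(b, dtype=np.float64)[oc]
    return out


def zero_inserted_kernel(w, dilation):
    """Expand a (…, k, k) kernel by inserting dilation-1 zero rows/cols
    between taps, so a dilated convolution equals a dense one with the
    expanded kernel."""
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[-1]
    ke = k + (k - 1) * (dilation - 1)
    out = np.zeros(w.shape[:-2] + (ke, ke))
    out[..., ::dilation, ::dilation] = w
    return out


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued f at float64 array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def check_grad(build_loss, arrays, rtol=2e-5, atol=1e-7):
    """Compare analytic and numerical gradients of a scalar loss.

    ``build_loss(tensors) -> Tensor`` receives float64 Tensors built from
    ``arrays`` (a dict name -> ndarray).  All analytic gradients are copied
    before any numerical evaluation mutates state.
    """
    tensors = {k: Tensor(np.asarray(v, dtype=np.float64), requires_grad=True)
               for k, v in arrays.items()}
    loss = build_loss(tensors)
    loss.backward()
    analytic = {k: t.grad.copy() for k, t in tensors.items()}

    for name, base in arrays.items():
        def f(x, name=name):
            local = {k: Tensor(np.asarray(v, dtype=np.float64))
                     for k, v in arrays.items()}
            local[name] = Tensor(np.asarray(x, dtype=np.float64))
            return build_loss(local).item()

        num = numeric_grad(f, base)
        np.testing.assert_allclose(
            analytic[name], num, rtol=rtol, atol=atol,
            err_msg=f"gradient mismatch for '{name}'")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
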