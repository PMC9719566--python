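"""Numerical core: convolution against a scipy oracle, analytic gradients
against finite differences, and the conv-LSTM step against a hand-computed
scalar LSTM."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from mirrornet._nn.convlstm import ConvLSTMParams, lstm_step_backward, lstm_step_forward
from mirrornet._nn.functional import (
    bce_with_logits,
    conv2d_backward,
    conv2d_forward,
    sigmoid,
)


def conv_oracle(x, w, dilation):
    """Direct same-padded dilated cross-correlation via scipy, one image/
    channel pair at a time (independent of the im2col path)."""
    n, h, wdt, c = x.shape
    o, _, k, _ = w.shape
    span = dilation * (k - 1) + 1
    kd = np.zeros((o, c, span, span))
    kd[:, :, ::dilation, ::dilation] = w
    out = np.zeros((n, h, wdt, o))
    for ni in range(n):
        for oi in range(o):
            for ci in range(c):
                out[ni, :, :, oi] += correlate2d(
                    x[ni, :, :, ci], kd[oi, ci], mode="same"
                )
    return out


class TestConv2d:
    @pytest.mark.parametrize("dilation", [1, 2, 4])
    def test_forward_matches_scipy(self, dilation, rng):
        x = rng.standard_normal((2, 11, 11, 3))
        w = rng.standard_normal((4, 3, 3, 3))
        got = conv2d_forward(x, w, None, dilation=dilation)
        np.testing.assert_allclose(got, conv_oracle(x, w, dilation), atol=1e-10)

    def test_bias_broadcast(self, rng):
        x = rng.standard_normal((1, 5, 5, 2))
        w = rng.standard_normal((3, 2, 3, 3))
        b = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(
            conv2d_forward(x, w, b), conv2d_forward(x, w, None) + b, atol=1e-12
        )

    @pytest.mark.parametrize("dilation", [1, 2])
    def test_gradients_finite_difference(self, dilation, rng):
        x = rng.standard_normal((2, 6, 6, 2))
        w = rng.standard_normal((3, 2, 3, 3)) * 0.5
        dy = rng.standard_normal((2, 6, 6, 3))
        dx, dw, db = conv2d_backward(dy, x, w, dilation=dilation)
        eps = 1e-6

        def loss(xx, ww):
            return float(np.sum(conv2d_forward(xx, ww, None, dilation) * dy))

        for arr, grad in ((x, dx), (w, dw)):
            for _ in range(6):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss(x, w)
                arr[ix] = orig - eps
                lm = loss(x, w)
                arr[ix] = orig
                np.testing.assert_allclose((lp - lm) / (2 * eps), grad[ix], rtol=1e-5)
        np.testing.assert_allclose(db, dy.sum(axis=(0, 1, 2)), atol=1e-10)


class TestConvLSTMStep:
    def test_zero_weights_zero_state_gives_zero_hidden(self):
        p = ConvLSTMParams(w=np.zeros((8, 3, 3, 3), np.float32),
                           b=np.zeros(8, np.float32))
        x = np.random.default_rng(0).standard_normal((2, 5, 5, 1)).astype(np.float32)
        h0 = np.zeros((2, 5, 5, 2), np.float32)
        h, c, _ = lstm_step_forward(x, h0, h0.copy(), p)
        assert np.all(h == 0) and np.all(c == 0)

    def test_determinism(self, rng):
        p = ConvLSTMParams.init(1, 3, 3, np.random.default_rng(1))
        x = rng.standard_normal((2, 7, 7, 1)).astype(np.float32)
        h0 = rng.standard_normal((2, 7, 7, 3)).astype(np.float32)
        c0 = rng.standard_normal((2, 7, 7, 3)).astype(np.float32)
        out1 = lstm_step_forward(x, h0, c0, p)
        out2 = lstm_step_forward(x, h0, c0, p)
        assert np.array_equal(out1[0], out2[0]) and np.array_equal(out1[1], out2[1])

    def test_matches_scalar_lstm_oracle(self):
        """1x1 kernel, 1 channel, 1x1 grid reduces to the textbook scalar
        LSTM equations, computed here by hand."""
        wi, wf, wg, wo = 0.3, -0.2, 0.5, 0.7  # input weights
        ui, uf, ug, uo = -0.4, 0.6, 0.1, -0.8  # recurrent weights
        bi, bf, bg, bo = 0.05, 1.0, -0.1, 0.2
        w = np.array(
            [[[[wi]], [[ui]]], [[[wf]], [[uf]]], [[[wg]], [[ug]]], [[[wo]], [[uo]]]],
            dtype=np.float64,
        )
        b = np.array([bi, bf, bg, bo], dtype=np.float64)
        p = ConvLSTMParams(w=w, b=b)
        xv, hv, cv = 0.9, -0.3, 0.4

        def sig(t):
            return 1.0 / (1.0 + np.exp(-t))

        i = sig(wi * xv + ui * hv + bi)
        f = sig(wf * xv + uf * hv + bf)
        g = np.tanh(wg * xv + ug * hv + bg)
        o = sig(wo * xv + uo * hv + bo)
        c_ref = f * cv + i * g
        h_ref = o * np.tanh(c_ref)

        x = np.full((1, 1, 1, 1), xv)
        h, c, _ = lstm_step_forward(x, np.full_like(x, hv), np.full_like(x, cv), p)
        np.testing.assert_allclose(h[0, 0, 0, 0], h_ref, atol=1e-6)
        np.testing.assert_allclose(c[0, 0, 0, 0], c_ref, atol=1e-6)

    def test_step_backward_finite_difference(self, rng):
        p = ConvLSTMParams.init(2, 2, 3, np.random.default_rng(3))
        p.w = p.w.astype(np.float64)
        p.b = p.b.astype(np.float64)
        x = rng.standard_normal((1, 4, 4, 2))
        h0 = rng.standard_normal((1, 4, 4, 2)) * 0.5
        c0 = rng.standard_normal((1, 4, 4, 2)) * 0.5
        dh = rng.standard_normal((1, 4, 4, 2))
        dc = rng.standard_normal((1, 4, 4, 2))

        def loss():
            h, c, _ = lstm_step_forward(x, h0, c0, p)
            return float(np.sum(h * dh) + np.sum(c * dc))

        _, _, cache = lstm_step_forward(x, h0, c0, p)
        dx, dh_prev, dc_prev, dw, db = lstm_step_backward(dh, dc, cache, p)
        eps = 1e-6
        for arr, grad in ((x, dx), (h0, dh_prev), (c0, dc_prev), (p.w, dw), (p.b, db)):
            for _ in range(5):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss()
                arr[ix] = orig - eps
                lm = loss()
                arr[ix] = orig
                np.testing.assert_allclose(
                    (lp - lm) / (2 * eps), grad[ix], rtol=2e-4, atol=1e-9
                )


class TestLossAndHelpers:
    def test_sigmoid_matches_logistic(self, rng):
        z = rng.standard_normal(100) * 8
        np.testing.assert_allclose(sigmoid(z), 1.0 / (1.0 + np.exp(-z)), atol=1e-12)

    def test_bce_matches_direct_formula(self, rng):
        z = rng.standard_normal(50) * 5
        y = rng.integers(0, 2, 50)
        loss, dz = bce_with_logits(z, y)
        p = 1.0 / (1.0 + np.exp(-z))
        ref = -np.mean(y * np.log(p) + (1 - y) * np.log1p(-p))
        np.testing.assert_allclose(loss, ref, rtol=1e-9)
        np.testing.assert_allclose(dz, (p - y) / 50, atol=1e-6)
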