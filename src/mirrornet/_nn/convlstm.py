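"""Convolutional LSTM cell: forward and backward through one time step.

Gate pre-activations are a single same-padded convolution over the
channel-concatenation of the step input and the previous hidden state:

    z = W * [x, h_{t-1}] + b,    z split into (i, f, g, o)
    i, f, o = sigmoid(.),  g = tanh(.)
    c_t = f . c_{t-1} + i . g
    h_t = o . tanh(c_t)

States are (N, H, W, C) float32 (channels last). The forget-gate bias is
initialised to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .functional import conv2d_backward, conv2d_forward, sigmoid


@dataclass
class ConvLSTMParams:
    """Weights of one cell: ``w`` is (4C, C_in + C, k, k), ``b`` is (4C,).

    Gate order along the leading axis: input, forget, cell (g), output.
    """

    w: np.ndarray
    b: np.ndarray

    @property
    def hidden_channels(self) -> int:
        return self.w.shape[0] // 4

    @property
    def input_channels(self) -> int:
        return self.w.shape[1] - self.hidden_channels

    @classmethod
    def init(
        cls,
        input_channels: int,
        hidden_channels: int,
        kernel: int,
        rng: np.random.Generator,
        forget_bias: float = 1.0,
    ) -> "ConvLSTMParams":
        fan_in = (input_channels + hidden_channels) * kernel * kernel
        w = rng.normal(
            0.0, 1.0 / np.sqrt(fan_in),
            size=(4 * hidden_channels, input_channels + hidden_channels, kernel, kernel),
        ).astype(np.float32)
        b = np.zeros(4 * hidden_channels, dtype=np.float32)
        b[hidden_channels : 2 * hidden_channels] = forget_bias
        return cls(w=w, b=b)


def lstm_step_forward(x, h_prev, c_prev, params: ConvLSTMParams,
                      with_cache: bool = True, store_cols: bool = False):
    """One time step. Returns ``(h, c, cache)``; ``cache`` holds what the
    backward pass needs (gates and cell states; optionally the patch matrix,
    a speed/memory trade-off for long unrolls)."""
    if x.shape[1:3] != h_prev.shape[1:3]:
        raise ValueError(f"spatial mismatch: x {x.shape} vs h {h_prev.shape}")
    ch = params.hidden_channels
    xh = np.concatenate([x, h_prev], axis=-1)
    z, cols = conv2d_forward(xh, params.w, params.b, return_cols=True) \
        if (with_cache and store_cols) else (conv2d_forward(xh, params.w, params.b), None)
    i = sigmoid(z[..., :ch])
    f = sigmoid(z[..., ch : 2 * ch])
    g = np.tanh(z[..., 2 * ch : 3 * ch])
    o = sigmoid(z[..., 3 * ch :])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    cache = (xh, cols, i, f, g, o, c_prev, tc) if with_cache else None
    return h, c, cache


def lstm_step_backward(dh, dc, cache, params: ConvLSTMParams, need_dx: bool = True):
    """Backward through one step.

    ``dh``/``dc`` are the gradients flowing into ``h_t``/``c_t`` (``dc``
    may be None). Returns ``(dx, dh_prev, dc_prev, dw, db)``.
    """
    xh, cols, i, f, g, o, c_prev, tc = cache
    nin = params.input_channels
    do = dh * tc
    dct = dh * o * (1.0 - tc * tc)
    if dc is not None:
        dct = dct + dc
    df = dct * c_prev
    dc_prev = dct * f
    di = dct * g
    dg = dct * i
    dz = np.concatenate(
        [
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ],
        axis=-1,
    ).astype(np.float32, copy=False)
    dxh, dw, db = conv2d_backward(dz, xh, params.w, dilation=1, need_dx=True, cols=cols)
    dx = dxh[..., :nin] if need_dx else None
    dh_prev = dxh[..., nin:]
    return dx, dh_prev, dc_prev, dw, db
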