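"""Functional kernels: same-padded stride-1 2-D convolution (with dilation)
as im2col + GEMM, logistic helpers, and the binary cross-entropy loss.

Internal layout is NHWC float32: patch extraction is then a near-contiguous
copy, the GEMM result needs no transpose, and the input gradient is a
nine-tap col2im scatter-add rather than a second convolution. Kernels are
odd-sized so "same" zero padding is symmetric.

Weights are stored (O, C, k, k) (output channels first) regardless of the
activation layout.
"""

from __future__ import annotations

import numpy as np

try:  # numba-fused gather/scatter kernels; numpy fallbacks below
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _im2col_nb(xp, n, h, w, c, k, dilation, out):  # pragma: no cover
        for ni in range(n):
            for hi in range(h):
                for wi in range(w):
                    row = (ni * h + hi) * w + wi
                    col = 0
                    for i in range(k):
                        for j in range(k):
                            for ci in range(c):
                                out[row, col] = xp[
                                    ni, hi + i * dilation, wi + j * dilation, ci
                                ]
                                col += 1

    @numba.njit(cache=True, fastmath=True)
    def _col2im_nb(dcols, n, h, w, c, k, dilation, dxp):  # pragma: no cover
        for ni in range(n):
            for hi in range(h):
                for wi in range(w):
                    row = (ni * h + hi) * w + wi
                    col = 0
                    for i in range(k):
                        for j in range(k):
                            for ci in range(c):
                                dxp[ni, hi + i * dilation, wi + j * dilation, ci] += (
                                    dcols[row, col]
                                )
                                col += 1

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def sigmoid(x: np.ndarray) -> np.ndarray:
    # 0.5 * (1 + tanh(x/2)): exact identity; numpy's tanh is SIMD-vectorised
    # while a 1/(1+exp(-x)) chain is several times slower at float32
    return 0.5 * np.tanh(0.5 * x) + 0.5


def _w2d(w: np.ndarray) -> np.ndarray:
    """(O, C, k, k) weights as an (O, k*k*C) matrix matching im2col rows."""
    o = w.shape[0]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1).reshape(o, -1))


def im2col(x: np.ndarray, kernel: int, dilation: int = 1) -> np.ndarray:
    """Extract sliding k x k patches of a same-padded NHWC array into a
    ``(N*H*W, k*k*C)`` matrix. Row layout is (kernel row, kernel column,
    channel) so the channel axis stays memory-contiguous during extraction."""
    n, h, w, c = x.shape
    pad = dilation * (kernel - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    if _HAVE_NUMBA and x.dtype == np.float32:
        out = np.empty((n * h * w, kernel * kernel * c), dtype=np.float32)
        _im2col_nb(xp, n, h, w, c, kernel, dilation, out)
        return out
    span = dilation * (kernel - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(1, 2))
    win = win[..., ::dilation, ::dilation]  # (n, h, w, c, k, k)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, kernel * kernel * c)
    return np.ascontiguousarray(cols)


def conv2d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    dilation: int = 1,
    return_cols: bool = False,
):
    """Same-padded stride-1 cross-correlation. ``x``: (N, H, W, C);
    ``w``: (O, C, k, k); returns (N, H, W, O) (and the im2col matrix when
    ``return_cols``)."""
    n, h, wdt, c = x.shape
    o, ci, kh, kw = w.shape
    if ci != c or kh != kw or kh % 2 != 1:
        raise ValueError(f"kernel/channel mismatch: x {x.shape}, w {w.shape}")
    cols = im2col(x, kh, dilation)
    y = cols @ _w2d(w).T
    if b is not None:
        y += b
    y = y.reshape(n, h, wdt, o)
    return (y, cols) if return_cols else y


def conv2d_backward(
    dy: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    dilation: int = 1,
    need_dx: bool = True,
    cols: np.ndarray | None = None,
):
    """Gradients of :func:`conv2d_forward`. Returns ``(dx, dw, db)``;
    ``dx`` is ``None`` when ``need_dx`` is false (first layer). Pass the
    forward pass's ``cols`` to avoid recomputing the patch matrix."""
    n, h, wdt, c = x.shape
    o, _, k, _ = w.shape
    dy_flat = dy.reshape(n * h * wdt, o)
    if cols is None:
        cols = im2col(x, k, dilation)
    dw = (dy_flat.T @ cols).reshape(o, k, k, c).transpose(0, 3, 1, 2)
    dw = np.ascontiguousarray(dw)
    db = dy_flat.sum(axis=0)
    dx = None
    if need_dx:
        dcols = dy_flat @ _w2d(w)
        pad = dilation * (k - 1) // 2
        dxp = np.zeros((n, h + 2 * pad, wdt + 2 * pad, c), dtype=dy.dtype)
        if _HAVE_NUMBA and dcols.dtype == np.float32:
            _col2im_nb(dcols, n, h, wdt, c, k, dilation, dxp)
        else:
            dc6 = dcols.reshape(n, h, wdt, k, k, c)
            for i in range(k):
                for j in range(k):
                    dxp[:, i * dilation : i * dilation + h,
                        j * dilation : j * dilation + wdt, :] += dc6[:, :, :, i, j, :]
        dx = dxp[:, pad : pad + h, pad : pad + wdt, :] if pad else dxp
    return dx, dw, db


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy from logits; returns ``(loss, dlogits)``.

    Numerically stable: loss_i = softplus(z) - y*z, softplus via logaddexp.
    """
    z = logits.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dlogits = ((sigmoid(z) - y) / len(z)).astype(np.float32)
    return loss, dlogits
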