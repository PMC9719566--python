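"""Minimal float32 neural-network kernels (im2col convolutions, conv-LSTM
cell, Adam) used by the classifier estimators."""

def _tune_allocator() -> None:
    """Raise glibc's mmap/trim thresholds so the large per-batch buffers are
    recycled from the heap instead of being mmap'd and unmapped every call
    (page-fault churn otherwise dominates the BLAS time). No-op elsewhere."""
    import ctypes

    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from .functional import conv2d_forward, conv2d_backward, sigmoid, bce_with_logits
from .convlstm import ConvLSTMParams, lstm_step_forward, lstm_step_backward
from .optim import Adam, clip_global_norm

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "sigmoid",
    "bce_with_logits",
    "ConvLSTMParams",
    "lstm_step_forward",
    "lstm_step_backward",
    "Adam",
    "clip_global_norm",
]
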