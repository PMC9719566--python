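"""Functional model surface: single-step cell application, step-restricted
forward passes, and closed-form receptive-field sizes.

These are thin wrappers over :mod:`mirrornet.estimators`; the estimator
classes own the parameters and the training loop.
"""

from __future__ import annotations

import numpy as np

from ._nn.convlstm import ConvLSTMParams, lstm_step_forward
from .estimators import ConvLSTMClassifier, DilatedConvClassifier
from .exceptions import InvalidSpecError


def convlstm_step(state, input_maps, params: ConvLSTMParams):
    """Apply one convolutional-LSTM step.

    ``state`` is an ``(hidden, cell)`` pair of channels-last (N, H, W, C)
    arrays and ``input_maps`` the step input; returns the new
    ``(hidden, cell)`` pair.
    """
    h, c = state
    h2, c2, _ = lstm_step_forward(
        np.asarray(input_maps, np.float32),
        np.asarray(h, np.float32),
        np.asarray(c, np.float32),
        params,
    )
    return h2, c2


def lstm3_forward(model: ConvLSTMClassifier, images, steps: int):
    """Step-restricted forward pass of a trained recurrent classifier.

    The same image is presented at every step and the shared readout is
    applied to the last cell's hidden state at step ``steps``. Returns
    ``(probabilities, hidden_sequence)`` where ``hidden_sequence`` has shape
    (n, steps, C, 20, 20).
    """
    if steps < 1:
        raise InvalidSpecError("steps must be >= 1")
    probs = model.predict_proba_steps(images, [steps])[:, 0]
    hidden = model.hidden_states(images, steps=list(range(1, steps + 1)), cell=-1)
    return probs, hidden


def dilated_forward(model: DilatedConvClassifier, images) -> np.ndarray:
    """Symmetric-class probability of the dilated feed-forward classifier."""
    return model.predict_proba(images)[:, 1]


def dilated_receptive_field(kernel_size: int, dilations) -> int:
    """RF of a stride-1 dilated stack: ``1 + sum((k - 1) * d)``."""
    return 1 + sum((kernel_size - 1) * int(d) for d in dilations)


def lstm_receptive_field(kernel_size: int, n_cells: int, steps: int) -> int:
    """RF of the unrolled recurrent stack after ``steps`` time steps: the
    field grows by ``(k - 1) * n_cells`` pixels per step."""
    if steps < 1:
        raise InvalidSpecError("steps must be >= 1")
    return 1 + (kernel_size - 1) * n_cells * steps


def receptive_field(model, steps: int | None = None) -> int:
    """Closed-form receptive field of either classifier."""
    if isinstance(model, DilatedConvClassifier):
        return dilated_receptive_field(model.kernel_size, model.dilations)
    if isinstance(model, ConvLSTMClassifier):
        return lstm_receptive_field(
            model.kernel_size, model.n_cells, steps or model.unroll_steps
        )
    raise InvalidSpecError(f"unsupported model type {type(model).__name__}")
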