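"""Scikit-learn style classifiers for pixel-level symmetry detection.

Two architectures are provided:

* :class:`ConvLSTMClassifier` — a stack of three convolutional LSTM cells.
  The same image is fed at every unrolling step, hidden state is carried
  across steps, and a dense readout of the last cell's final hidden state
  yields the symmetry probability. Recurrence lets the network decompose the
  long-range left/right comparison into repeated local operations.
* :class:`DilatedConvClassifier` — a feed-forward stack of same-padded 3x3
  convolutions whose dilation rates expand the receptive field beyond the
  image size, followed by the same dense readout.

Both train from scratch with mini-batch binary cross-entropy; inputs are
20x20 gray-level images in [0, 255], normalised internally to [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn.convlstm import ConvLSTMParams, lstm_step_backward, lstm_step_forward
from ._nn.functional import bce_with_logits, conv2d_backward, conv2d_forward
from ._nn.optim import SGD, Adam, clip_global_norm
from .exceptions import InvalidDataError, InvalidSpecError

IMAGE_SIZE = 20
_EVAL_CHUNK = 512


def _as_image_batch(X: np.ndarray) -> np.ndarray:
    """Coerce (n, 20, 20) or (n, 400) gray-level input to a normalised
    channels-last (n, 20, 20, 1) float32 batch."""
    X = np.asarray(X)
    if X.ndim == 2 and X.shape[1] == IMAGE_SIZE * IMAGE_SIZE:
        X = X.reshape(-1, IMAGE_SIZE, IMAGE_SIZE)
    if X.ndim != 3 or X.shape[1:] != (IMAGE_SIZE, IMAGE_SIZE):
        raise InvalidDataError(
            f"expected (n, {IMAGE_SIZE}, {IMAGE_SIZE}) or (n, {IMAGE_SIZE**2}) input, "
            f"got shape {X.shape}"
        )
    return (X.astype(np.float32) / np.float32(255.0))[..., None]


class _SymmetryNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared training loop, scoring and persistence for both architectures."""

    def __init__(
        self,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 50,
        patience: int = 5,
        optimizer: str = "adam",
        clip_norm: float = 0.0,
        lr_decay: float = 1.0,
        validation_fraction: float = 0.05,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.optimizer = optimizer
        self.clip_norm = clip_norm
        self.lr_decay = lr_decay
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- subclass hooks ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        raise NotImplementedError

    def _forward(self, xb: np.ndarray, params: list[np.ndarray], with_cache: bool):
        """Return ``(logits, cache)`` for a normalised channels-last batch."""
        raise NotImplementedError

    def _backward(self, dlogits, cache, params) -> list[np.ndarray]:
        raise NotImplementedError

    # -- training ----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on gray-level images ``X`` with binary labels ``y``
        (1 = symmetric). An explicit validation set may be supplied;
        otherwise ``validation_fraction`` is carved from ``X``."""
        y = np.asarray(y).astype(np.int64).ravel()
        Xn = _as_image_batch(X)
        if len(Xn) != len(y):
            raise InvalidDataError("X and y length mismatch")
        classes = np.unique(y)
        if not np.array_equal(np.unique(classes), classes) or classes.size < 2:
            raise InvalidDataError("training data must contain both classes")
        if not set(classes).issubset({0, 1}):
            raise InvalidDataError("labels must be binary (0/1)")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = IMAGE_SIZE * IMAGE_SIZE

        ss = np.random.SeedSequence(self.random_state)
        init_rng, shuffle_rng, split_rng = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )

        if X_val is not None:
            Xv, yv = _as_image_batch(X_val), np.asarray(y_val).astype(np.int64).ravel()
        elif self.validation_fraction and self.validation_fraction > 0:
            order = split_rng.permutation(len(Xn))
            n_val = max(1, int(round(len(Xn) * self.validation_fraction)))
            if n_val >= len(Xn):
                raise InvalidDataError("validation_fraction leaves no training data")
            Xv, yv = Xn[order[:n_val]], y[order[:n_val]]
            Xn, y = Xn[order[n_val:]], y[order[n_val:]]
        else:
            Xv = yv = None

        params = self._init_params(init_rng)
        opt_cls = {"adam": Adam, "sgd": SGD}.get(self.optimizer)
        if opt_cls is None:
            raise InvalidSpecError(f"unknown optimizer {self.optimizer!r}")
        opt = opt_cls(params, lr=self.learning_rate)

        history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        best_val, best_params, best_epoch = -np.inf, None, -1
        self.diverged_ = False
        n = len(Xn)
        for epoch in range(self.max_epochs):
            order = shuffle_rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xn[idx], y[idx]
                logits, cache = self._forward(xb, params, with_cache=True)
                loss, dlogits = bce_with_logits(logits, yb)
                if not np.isfinite(loss):
                    self.diverged_ = True
                    break
                losses.append(loss)
                correct += int(np.sum((logits > 0).astype(np.int64) == yb))
                grads = self._backward(dlogits, cache, params)
                if self.clip_norm and self.clip_norm > 0:
                    clip_global_norm(grads, self.clip_norm)
                opt.step(grads)
            if self.diverged_:
                break
            # per-epoch learning-rate anneal (1.0 = constant)
            opt.lr *= self.lr_decay
            history["train_loss"].append(float(np.mean(losses)))
            history["train_acc"].append(correct / n)
            if Xv is not None:
                vl, va = self._eval_loss_acc(Xv, yv, params)
                history["val_loss"].append(vl)
                history["val_acc"].append(va)
                if self.verbose:
                    print(
                        f"epoch {epoch}: train_loss={history['train_loss'][-1]:.4f} "
                        f"val_acc={va:.4f}"
                    )
                if va > best_val:
                    best_val, best_epoch = va, epoch
                    best_params = [p.copy() for p in params]
                if self.patience and epoch - best_epoch >= self.patience:
                    break
                if va >= 1.0 and history["train_acc"][-1] >= 1.0:
                    break

        if best_params is not None:
            params = best_params
        self.params_ = params
        self.history_ = history
        self.best_validation_accuracy_ = (
            float(best_val) if np.isfinite(best_val) else float("nan")
        )
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _eval_loss_acc(self, Xn, y, params):
        logits = self._decision_from_normalised(Xn, params)
        loss, _ = bce_with_logits(logits, y)
        acc = float(np.mean((logits > 0).astype(np.int64) == y))
        return loss, acc

    # -- inference ---------------------------------------------------------
    def _decision_from_normalised(self, Xn, params=None, **kw) -> np.ndarray:
        params = self.params_ if params is None else params
        out = np.empty(len(Xn), dtype=np.float64)
        for s in range(0, len(Xn), _EVAL_CHUNK):
            logits, _ = self._forward(Xn[s : s + _EVAL_CHUNK], params, with_cache=False, **kw)
            out[s : s + len(logits)] = logits
        return out

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self._decision_from_normalised(_as_image_batch(X))

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        """Predict 1 (symmetric) when the probability strictly exceeds 0.5;
        exact ties count as non-symmetric."""
        return (self.decision_function(X) > 0.0).astype(np.int64)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise InvalidDataError(f"{type(self).__name__} is not fitted")

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Write a single-file weight archive with a JSON spec header."""
        import json
        from pathlib import Path

        path = Path(path)
        self._check_fitted()
        header = {"class": type(self).__name__, "params": self.get_params()}
        arrays = {f"p{i}": p for i, p in enumerate(self.params_)}
        np.savez_compressed(path, header=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "_SymmetryNetClassifier":
        import json

        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            arrays = [data[f"p{i}"] for i in range(sum(k.startswith("p") and k != "header" for k in data.files))]
        klass = {c.__name__: c for c in (ConvLSTMClassifier, DilatedConvClassifier)}[
            header["class"]
        ]
        est = klass(**header["params"])
        est.classes_ = np.array([0, 1])
        est.params_ = [np.asarray(a) for a in arrays]
        est.history_ = {}
        est.best_validation_accuracy_ = float("nan")
        return est


class ConvLSTMClassifier(_SymmetryNetClassifier):
    """Three stacked convolutional LSTM cells with a dense sigmoid readout.

    Parameters
    ----------
    n_channels : hidden channels per cell (64 at full scale, 16 scaled down)
    n_cells : number of stacked cells (3)
    kernel_size : spatial kernel of every gate convolution (3)
    unroll_steps : training-time number of time steps T; at inference the
        forward pass may be truncated to fewer steps (or extended to more),
        reusing the same trained readout on the truncated final hidden state.
    clip_norm : global gradient-norm clip protecting the unrolled backward
        pass (1.0 by default).
    """

    def __init__(
        self,
        n_channels: int = 64,
        n_cells: int = 3,
        kernel_size: int = 3,
        unroll_steps: int = 20,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 50,
        patience: int = 5,
        optimizer: str = "adam",
        clip_norm: float = 1.0,
        lr_decay: float = 1.0,
        validation_fraction: float = 0.05,
        random_state: int = 0,
        verbose: int = 0,
    ):
        super().__init__(
            learning_rate=learning_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            patience=patience,
            optimizer=optimizer,
            clip_norm=clip_norm,
            lr_decay=lr_decay,
            validation_fraction=validation_fraction,
            random_state=random_state,
            verbose=verbose,
        )
        self.n_channels = n_channels
        self.n_cells = n_cells
        self.kernel_size = kernel_size
        self.unroll_steps = unroll_steps

    @property
    def is_recurrent(self) -> bool:
        return True

    def _init_params(self, rng) -> list[np.ndarray]:
        if self.unroll_steps < 1:
            raise InvalidSpecError("unroll_steps must be >= 1")
        params: list[np.ndarray] = []
        in_ch = 1
        for _ in range(self.n_cells):
            cell = ConvLSTMParams.init(in_ch, self.n_channels, self.kernel_size, rng)
            params.extend([cell.w, cell.b])
            in_ch = self.n_channels
        d = self.n_channels * IMAGE_SIZE * IMAGE_SIZE
        params.append((rng.normal(0, 1.0 / np.sqrt(d), size=d)).astype(np.float32))
        params.append(np.zeros(1, dtype=np.float32))
        return params

    def _cells(self, params) -> list[ConvLSTMParams]:
        return [
            ConvLSTMParams(w=params[2 * k], b=params[2 * k + 1])
            for k in range(self.n_cells)
        ]

    def _forward(self, xb, params, with_cache: bool, max_steps: int | None = None,
                 collect: str | None = None, collect_cell: int = -1):
        """Unrolled forward pass.

        ``collect`` may be ``"logits"`` (per-step readout logits) or
        ``"hidden"`` (per-step hidden state of ``collect_cell``); the
        collected sequence is then returned inside the cache slot.
        """
        steps = self.unroll_steps if max_steps is None else int(max_steps)
        if steps < 1:
            raise InvalidSpecError("number of time steps must be >= 1")
        cells = self._cells(params)
        w_out, b_out = params[-2], params[-1]
        n = len(xb)
        h = [
            np.zeros((n, IMAGE_SIZE, IMAGE_SIZE, self.n_channels), np.float32)
            for _ in range(self.n_cells)
        ]
        c = [np.zeros_like(h[0]) for _ in range(self.n_cells)]
        caches = [] if with_cache else None
        collected = [] if collect else None
        for _t in range(steps):
            x = xb
            step_caches = [] if with_cache else None
            for k, cell in enumerate(cells):
                h[k], c[k], cache = lstm_step_forward(x, h[k], c[k], cell, with_cache=with_cache)
                if with_cache:
                    step_caches.append(cache)
                x = h[k]
            if with_cache:
                caches.append(step_caches)
            if collect == "logits":
                collected.append(
                    h[-1].reshape(n, -1) @ w_out + b_out[0]
                )
            elif collect == "hidden":
                collected.append(h[collect_cell].copy())
        h_final = h[-1].reshape(n, -1)
        logits = h_final @ w_out + b_out[0]
        return logits, (caches, h_final, collected, steps)

    def _backward(self, dlogits, cache, params):
        caches, h_final, _, steps = cache
        cells = self._cells(params)
        w_out = params[-2]
        grads = [np.zeros_like(p) for p in params]
        grads[-2] = (h_final.T @ dlogits).astype(np.float32)
        grads[-1] = np.array([dlogits.sum()], dtype=np.float32)
        dh_readout = np.outer(dlogits, w_out).reshape(
            -1, IMAGE_SIZE, IMAGE_SIZE, self.n_channels
        ).astype(np.float32)
        dh_carry = [None] * self.n_cells
        dc_carry = [None] * self.n_cells
        for t in reversed(range(steps)):
            dx_down = None
            for k in reversed(range(self.n_cells)):
                dh = dh_carry[k]
                if dx_down is not None:
                    dh = dx_down if dh is None else dh + dx_down
                if k == self.n_cells - 1 and t == steps - 1:
                    dh = dh_readout if dh is None else dh + dh_readout
                if dh is None:
                    dh = np.zeros_like(dh_readout)
                dx, dh_prev, dc_prev, dw, db = lstm_step_backward(
                    dh, dc_carry[k], caches[t][k], cells[k], need_dx=(k > 0)
                )
                grads[2 * k] += dw
                grads[2 * k + 1] += db
                dh_carry[k], dc_carry[k] = dh_prev, dc_prev
                dx_down = dx
        return grads

    # -- recurrent-specific inference -------------------------------------
    def decision_function(self, X, max_steps: int | None = None) -> np.ndarray:
        """Readout logit after ``max_steps`` unrolling steps (default: the
        training step count)."""
        self._check_fitted()
        return self._decision_from_normalised(_as_image_batch(X), max_steps=max_steps)

    def decision_function_steps(self, X, steps: list[int]) -> np.ndarray:
        """Logits at several step budgets in one pass; returns (n, len(steps)).

        A single forward run to ``max(steps)`` suffices because truncated
        runs share their hidden-state prefix with longer runs.
        """
        self._check_fitted()
        steps = [int(s) for s in steps]
        if any(s < 1 for s in steps):
            raise InvalidSpecError("step budgets must be >= 1")
        Xn = _as_image_batch(X)
        out = np.empty((len(Xn), len(steps)), dtype=np.float64)
        for s0 in range(0, len(Xn), _EVAL_CHUNK):
            _, (_, _, per_step, _) = self._forward(
                Xn[s0 : s0 + _EVAL_CHUNK],
                self.params_,
                with_cache=False,
                max_steps=max(steps),
                collect="logits",
            )
            for j, s in enumerate(steps):
                out[s0 : s0 + len(per_step[0]), j] = per_step[s - 1]
        return out

    def predict_proba_steps(self, X, steps: list[int]) -> np.ndarray:
        """Probability of the symmetric class at each step budget."""
        return expit(self.decision_function_steps(X, steps))

    def hidden_states(self, X, steps: list[int] | None = None, cell: int = -1) -> np.ndarray:
        """Hidden-state maps of ``cell`` at the requested time steps.

        Returns (n, len(steps), C, 20, 20); default is the final training
        step of the last cell (the representation read out by the head).
        """
        self._check_fitted()
        steps = [self.unroll_steps] if steps is None else [int(s) for s in steps]
        if any(not 1 <= s for s in steps):
            raise InvalidSpecError("time steps must be >= 1")
        Xn = _as_image_batch(X)
        out = None
        for s0 in range(0, len(Xn), _EVAL_CHUNK):
            _, (_, _, hidden, _) = self._forward(
                Xn[s0 : s0 + _EVAL_CHUNK],
                self.params_,
                with_cache=False,
                max_steps=max(steps),
                collect="hidden",
                collect_cell=cell,
            )
            sel = np.stack([hidden[s - 1] for s in steps], axis=1)
            sel = sel.transpose(0, 1, 4, 2, 3)  # -> (n, steps, C, H, W)
            if out is None:
                out = np.empty((len(Xn),) + sel.shape[1:], dtype=np.float32)
            out[s0 : s0 + len(sel)] = sel
        return out

    def representations(self, X, max_steps: int | None = None) -> np.ndarray:
        """Flattened final hidden state of the last cell — the activation
        vector consumed by the readout (used for RSA)."""
        h = self.hidden_states(
            X, steps=[max_steps or self.unroll_steps], cell=-1
        )[:, 0]
        return h.reshape(len(h), -1)


class DilatedConvClassifier(_SymmetryNetClassifier):
    """Feed-forward dilated-convolution classifier.

    Seven same-padded 3x3 convolution + ReLU layers whose dilation rates
    (default ``(1, 2, 4, 4, 4, 4, 4)``) expand the receptive field past the
    20-pixel image extent, followed by a dense sigmoid readout. Construction
    rejects schedules whose receptive field is below the image size.
    """

    def __init__(
        self,
        n_channels: int = 64,
        dilations: tuple[int, ...] = (1, 2, 4, 4, 4, 4, 4),
        kernel_size: int = 3,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 50,
        patience: int = 5,
        optimizer: str = "adam",
        clip_norm: float = 0.0,
        lr_decay: float = 1.0,
        validation_fraction: float = 0.05,
        random_state: int = 0,
        verbose: int = 0,
    ):
        super().__init__(
            learning_rate=learning_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            patience=patience,
            optimizer=optimizer,
            clip_norm=clip_norm,
            lr_decay=lr_decay,
            validation_fraction=validation_fraction,
            random_state=random_state,
            verbose=verbose,
        )
        self.n_channels = n_channels
        self.dilations = dilations
        self.kernel_size = kernel_size

    @property
    def is_recurrent(self) -> bool:
        return False

    def receptive_field(self) -> int:
        from .models import dilated_receptive_field

        return dilated_receptive_field(self.kernel_size, self.dilations)

    def _init_params(self, rng) -> list[np.ndarray]:
        if len(self.dilations) < 1 or any(d < 1 for d in self.dilations):
            raise InvalidSpecError("dilations must be positive integers")
        if self.receptive_field() < IMAGE_SIZE:
            raise InvalidSpecError(
                f"dilation schedule {self.dilations} gives receptive field "
                f"{self.receptive_field()} < {IMAGE_SIZE}"
            )
        params: list[np.ndarray] = []
        in_ch = 1
        k = self.kernel_size
        for _ in self.dilations:
            fan_in = in_ch * k * k
            # He initialisation for the ReLU stack
            params.append(
                rng.normal(0, np.sqrt(2.0 / fan_in),
                           size=(self.n_channels, in_ch, k, k)).astype(np.float32)
            )
            params.append(np.zeros(self.n_channels, dtype=np.float32))
            in_ch = self.n_channels
        d = self.n_channels * IMAGE_SIZE * IMAGE_SIZE
        params.append((rng.normal(0, 1.0 / np.sqrt(d), size=d)).astype(np.float32))
        params.append(np.zeros(1, dtype=np.float32))
        return params

    def _forward(self, xb, params, with_cache: bool):
        acts = [xb]
        x = xb
        for i, dil in enumerate(self.dilations):
            z = conv2d_forward(x, params[2 * i], params[2 * i + 1], dilation=dil)
            x = np.maximum(z, 0.0)
            if with_cache:
                acts.append(x)
        feat = x.reshape(len(xb), -1)
        logits = feat @ params[-2] + params[-1][0]
        return logits, (acts, feat, x)

    def _backward(self, dlogits, cache, params):
        acts, feat, _ = cache
        grads = [np.zeros_like(p) for p in params]
        grads[-2] = (feat.T @ dlogits).astype(np.float32)
        grads[-1] = np.array([dlogits.sum()], dtype=np.float32)
        dx = np.outer(dlogits, params[-2]).reshape(acts[-1].shape).astype(np.float32)
        for i in reversed(range(len(self.dilations))):
            dz = dx * (acts[i + 1] > 0)
            dx, dw, db = conv2d_backward(
                dz, acts[i], params[2 * i], dilation=self.dilations[i], need_dx=(i > 0)
            )
            grads[2 * i], grads[2 * i + 1] = dw, db
        return grads

    def representations(self, X) -> np.ndarray:
        """Flattened output of the last ReLU layer (pre-readout activations)."""
        self._check_fitted()
        Xn = _as_image_batch(X)
        out = np.empty((len(Xn), self.n_channels * IMAGE_SIZE**2), np.float32)
        for s in range(0, len(Xn), _EVAL_CHUNK):
            _, (_, feat, _) = self._forward(Xn[s : s + _EVAL_CHUNK], self.params_, False)
            out[s : s + len(feat)] = feat
        return out
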