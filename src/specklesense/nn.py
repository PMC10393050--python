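"""Compact numpy CNN→LSTM classifier for frame-difference sequences.

The network mirrors the sequence-classification flow used for the deep
back-end: a sequence of difference images is folded into a batch of images,
a small convolutional extractor (2 conv+ReLU+maxpool blocks) turns each
frame into a feature vector, the sequence structure is restored (unfold +
flatten), an LSTM consumes the vector sequence, and a softmax layer over the
glucose classes reads out the final hidden state. Training uses Adam with
gradient-norm clipping, mini-batches and per-epoch shuffling.

Everything — forward pass, backpropagation (including BPTT through the
LSTM), and the optimizer — is implemented directly on numpy arrays; the
model is deliberately small (a few thousand parameters at the default
sizes) and float64 throughout for reproducibility.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .models import DifferenceSequence, TrainConfig

__all__ = ["CNNLSTMClassifier", "FitHistory", "train_cnn_lstm"]


# ---------------------------------------------------------------------------
# layer primitives (stride-1 'same' convolution, 2x2 max pooling, LSTM)

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (N, C, H, W); w: (F, C, 3, 3); 'same' padding, stride 1."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # windows: (N, C, H, W, 3, 3) -> columns (N*H*W, C*9)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    wmat = w.reshape(f, c * 9)
    out = cols @ wmat.T + b
    out = out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, wmat)


def _conv_backward(dout: np.ndarray, cache):
    cols, x_shape, wmat = cache
    n, c, h, wd = x_shape
    f = wmat.shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
    dw = (dmat.T @ cols).reshape(f, c, 3, 3)
    db = dmat.sum(axis=0)
    dcols = dmat @ wmat  # (N*H*W, C*9)
    dcols = dcols.reshape(n, h, wd, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, wd + 2))
    for dy in range(3):
        for dx in range(3):
            dxp[:, :, dy : dy + h, dx : dx + wd] += dcols[:, :, :, :, dy, dx].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1 : 1 + h, 1 : 1 + wd], dw, db


def _pool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xt = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    out = xt.max(axis=(3, 5))
    mask = xt == out[:, :, :, None, :, None]
    return out, (mask, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    mask, x_shape = cache
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(x_shape)
    spread = mask * dout[:, :, :, None, :, None]
    dx[:, :, : 2 * h2, : 2 * w2] = spread.reshape(n, c, 2 * h2, 2 * w2)
    return dx


def _lstm_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, hidden: int):
    """x: (B, T, D); returns final hidden state and per-step caches."""
    bsz, steps, _ = x.shape
    h = np.zeros((bsz, hidden))
    c = np.zeros((bsz, hidden))
    caches = []
    for t in range(steps):
        concat = np.concatenate([h, x[:, t, :]], axis=1)
        z = concat @ w + b
        i = _sigmoid(z[:, :hidden])
        f = _sigmoid(z[:, hidden : 2 * hidden])
        o = _sigmoid(z[:, 2 * hidden : 3 * hidden])
        g = np.tanh(z[:, 3 * hidden :])
        c_next = f * c + i * g
        h_next = o * np.tanh(c_next)
        caches.append((concat, i, f, o, g, c, c_next))
        h, c = h_next, c_next
    return h, caches


def _lstm_backward(dh_last: np.ndarray, caches, w: np.ndarray, hidden: int):
    bsz = dh_last.shape[0]
    steps = len(caches)
    d_in = caches[0][0].shape[1] - hidden
    dw = np.zeros_like(w)
    db = np.zeros(w.shape[1])
    dx = np.zeros((bsz, steps, d_in))
    dh = dh_last
    dc = np.zeros((bsz, hidden))
    for t in range(steps - 1, -1, -1):
        concat, i, f, o, g, c_prev, c_next = caches[t]
        tanh_c = np.tanh(c_next)
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g * g),
            ],
            axis=1,
        )
        dw += concat.T @ dz
        db += dz.sum(axis=0)
        dconcat = dz @ w.T
        dh = dconcat[:, :hidden]
        dx[:, t, :] = dconcat[:, hidden:]
        dc = dc * f
    return dx, dw, db


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class FitHistory:
    """Per-epoch training record."""

    loss: list
    accuracy: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.loss) + 1), "loss": self.loss,
             "accuracy": self.accuracy}
        )


class CNNLSTMClassifier:
    """Sequence classifier: fold → conv blocks → unfold/flatten → LSTM → softmax."""

    def __init__(
        self,
        frame_shape: tuple[int, int],
        n_classes: int,
        conv_channels: tuple[int, int] = (8, 16),
        lstm_hidden: int = 32,
        seed: int = 0,
    ):
        self.frame_shape = tuple(frame_shape)
        self.n_classes = int(n_classes)
        self.conv_channels = tuple(conv_channels)
        self.lstm_hidden = int(lstm_hidden)
        self.seed = int(seed)
        self.classes_: np.ndarray | None = None

        h, w = self.frame_shape
        c1, c2 = self.conv_channels
        self.feat_dim = c2 * (h // 4) * (w // 4)
        if self.feat_dim == 0:
            raise InvalidInputError("frames too small for two 2x2 pooling stages")

        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        hid = self.lstm_hidden
        self.params = {
            "conv1_w": he((c1, 1, 3, 3), 9),
            "conv1_b": np.zeros(c1),
            "conv2_w": he((c2, c1, 3, 3), 9 * c1),
            "conv2_b": np.zeros(c2),
            "lstm_w": rng.standard_normal((hid + self.feat_dim, 4 * hid))
            / np.sqrt(hid + self.feat_dim),
            "lstm_b": np.zeros(4 * hid),
            "out_w": he((hid, self.n_classes), hid),
            "out_b": np.zeros(self.n_classes),
        }
        # forget-gate bias starts positive: keeps memory early in training
        self.params["lstm_b"][hid : 2 * hid] = 1.0
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray):
        """x: (B, T, H, W) → class probabilities (B, K) plus caches."""
        b, t, h, w = x.shape
        folded = x.reshape(b * t, 1, h, w)
        a1, cache1 = _conv_forward(folded, self.params["conv1_w"], self.params["conv1_b"])
        r1 = np.maximum(a1, 0.0)
        p1, cachep1 = _pool_forward(r1)
        a2, cache2 = _conv_forward(p1, self.params["conv2_w"], self.params["conv2_b"])
        r2 = np.maximum(a2, 0.0)
        p2, cachep2 = _pool_forward(r2)
        feats = p2.reshape(b, t, self.feat_dim)
        h_last, lstm_caches = _lstm_forward(
            feats, self.params["lstm_w"], self.params["lstm_b"], self.lstm_hidden
        )
        logits = h_last @ self.params["out_w"] + self.params["out_b"]
        probs = _softmax(logits)
        caches = (cache1, a1, cachep1, cache2, a2, cachep2, p2.shape,
                  lstm_caches, h_last, (b, t, h, w))
        return probs, caches

    def _backward(self, probs: np.ndarray, y_idx: np.ndarray, caches):
        (cache1, a1, cachep1, cache2, a2, cachep2, p2_shape,
         lstm_caches, h_last, dims) = caches
        b, t, h, w = dims
        grads = {}
        dlogits = probs.copy()
        dlogits[np.arange(b), y_idx] -= 1.0
        dlogits /= b
        grads["out_w"] = h_last.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dh_last = dlogits @ self.params["out_w"].T
        dfeats, grads["lstm_w"], grads["lstm_b"] = _lstm_backward(
            dh_last, lstm_caches, self.params["lstm_w"], self.lstm_hidden
        )
        dp2 = dfeats.reshape(p2_shape)
        dr2 = _pool_backward(dp2, cachep2)
        da2 = dr2 * (a2 > 0)
        dp1, grads["conv2_w"], grads["conv2_b"] = _conv_backward(da2, cache2)
        dr1 = _pool_backward(dp1, cachep1)
        da1 = dr1 * (a1 > 0)
        _, grads["conv1_w"], grads["conv1_b"] = _conv_backward(da1, cache1)
        return grads

    def _adam_step(self, grads: dict, lr: float, clip: float) -> None:
        norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        if clip > 0 and norm > clip:
            scale = clip / norm
            grads = {k: g * scale for k, g in grads.items()}
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def fit(self, sequences: np.ndarray, labels: Sequence, config: TrainConfig) -> FitHistory:
        """Train on (B, T, H, W) sequences; returns the per-epoch history."""
        x = _as_sequence_array(sequences, self.frame_shape)
        labels = np.asarray(labels)
        if labels.shape[0] != x.shape[0]:
            raise InvalidInputError("one label per sequence required")
        self.classes_ = np.unique(labels)
        if self.classes_.size > self.n_classes:
            raise InvalidInputError("more label values than output classes")
        lut = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([lut[v] for v in labels])

        rng = np.random.default_rng(config.seed)
        n = x.shape[0]
        history = FitHistory(loss=[], accuracy=[])
        for _ in range(config.epochs):
            order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                probs, caches = self._forward(x[batch])
                p_true = np.clip(probs[np.arange(len(batch)), y_idx[batch]], 1e-12, 1.0)
                epoch_loss += float(-np.log(p_true).sum())
                correct += int((probs.argmax(axis=1) == y_idx[batch]).sum())
                grads = self._backward(probs, y_idx[batch], caches)
                self._adam_step(grads, config.learning_rate, config.gradient_threshold)
            history.loss.append(epoch_loss / n)
            history.accuracy.append(correct / n)
        return history

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        x = _as_sequence_array(sequences, self.frame_shape)
        probs, _ = self._forward(x)
        return probs

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        x = _as_sequence_array(sequences, self.frame_shape)
        if x.shape[0] == 0:
            return np.empty((0,))
        probs = self.predict_proba(x)
        idx = probs.argmax(axis=1)
        if self.classes_ is not None and self.classes_.size == self.n_classes:
            return self.classes_[idx]
        if self.classes_ is not None:
            padded = np.concatenate(
                [self.classes_,
                 np.full(self.n_classes - self.classes_.size, self.classes_[-1])]
            )
            return padded[idx]
        return idx

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "CNNLSTMClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _as_sequence_array(sequences, frame_shape: tuple[int, int]) -> np.ndarray:
    """Validate and stack sequences to (B, T, H, W)."""
    if isinstance(sequences, np.ndarray):
        x = sequences.astype(np.float64)
    else:
        stacks = [
            s.frames if isinstance(s, DifferenceSequence) else np.asarray(s)
            for s in sequences
        ]
        lengths = {s.shape for s in stacks}
        if len(lengths) > 1:
            raise InvalidInputError(f"inconsistent sequence shapes: {sorted(lengths)}")
        x = np.stack(stacks).astype(np.float64)
    if x.ndim != 4:
        raise InvalidInputError("sequences must stack to (B, T, H, W)")
    if x.shape[0] and x.shape[2:] != tuple(frame_shape):
        raise InvalidInputError(
            f"frame shape {x.shape[2:]} does not match model {frame_shape}"
        )
    return x


def train_cnn_lstm(
    sequences,
    labels: Sequence,
    config: TrainConfig,
    conv_channels: tuple[int, int] = (8, 16),
    lstm_hidden: int = 32,
) -> tuple[CNNLSTMClassifier, FitHistory]:
    """Build and train a CNN→LSTM on difference-image sequences."""
    first = sequences[0]
    frames = first.frames if isinstance(first, DifferenceSequence) else np.asarray(first)
    frame_shape = frames.shape[-2:]
    classes = np.unique(np.asarray(labels))
    model = CNNLSTMClassifier(
        frame_shape=frame_shape,
        n_classes=classes.size,
        conv_channels=conv_channels,
        lstm_hidden=lstm_hidden,
        seed=config.seed,
    )
    history = model.fit(sequences, labels, config)
    return model, history
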